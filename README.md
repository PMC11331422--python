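# paralogsel

Selection-divergence analysis for a duplicated gene pair, built around four
independently runnable stages:

1. **Trait extraction** — call a binary residue trait (present / absent /
   unknown) per sequence from a protein MSA, at the alignment column
   homologous to a reference residue (e.g. the Asp at reference position 338).
2. **Trait-model comparison** — two-state CTMC on a rooted phylogeny with a
   gain rate `q01`, a loss rate `q10`, and an optional class-specific loss
   rate `q10_delta` on tagged clades. Felsenstein-pruning likelihood, ML
   fitting, nested LRT (χ², 1 df), Metropolis–Hastings MCMC with
   exponential(mean 0.1) priors, node fossilization (fixing an ancestral
   state), stepping-stone log marginal likelihoods, and log Bayes factors
   (2×ΔlogML; ≤2 weak, >2 positive, >5 strong).
3. **Site-level dN/dS** — MG94×HKY codon model with F3x4 frequencies; FEL-style
   per-site tests of β=α on a selected branch partition, and a
   Contrast-FEL-style test of β_α=β_δ with a shared synonymous rate.
4. **Physiology & expression** — Na⁺ self-inhibition fraction
   `(I_peak − I_ss)/(I_peak − I_amil)` from annotated voltage-clamp traces,
   t-test / ANOVA + Šidák group comparisons, and RPKM/FPKM expression calls
   with the 0.3 background threshold.

A `simulate` module generates every input class (Yule trees with a tagged
δ clade, event-driven trait simulation, codon alignments with
partition-specific ω, current traces with peak → exponential decay →
amiloride baseline, count tables), so the whole pipeline is testable offline.

## CLI

```bash
paralogsel traits --msa msa.fasta --reference-id HUMAN_ALPHA --position 338 \
    --target-residue D --out traits.csv
paralogsel trait-model --config trait.yaml --seed 1 --outdir out/
paralogsel fel --config selection.yaml --outdir out/
paralogsel ssi --config physiology.yaml --outdir out/
paralogsel simulate --outdir synthetic/ --seed 1 --n-tips 50
```

Configs are YAML with one block per stage; unknown keys are rejected. See
`tests/test_pipeline.py` for minimal working configs. Exit codes: 0 success,
2 config error, 3 stage failure.

Example trait-model config:

```yaml
tree: tree.nwk
traits: traits.csv            # or: msa + site {reference_id, position, ...}
branch_classes:
  - {class: delta, taxa: [speciesA_delta, speciesB_delta]}
constraints:
  - {name: anc_present, taxa: [lamprey_alpha, coelacanth_alpha], state: present}
  - {name: anc_absent,  taxa: [lamprey_alpha, coelacanth_alpha], state: absent}
mcmc: {iterations: 1010000, burn_in: 10000, thinning: 1000}
stepping_stone: {n_stones: 100, iterations_per_stone: 10000}
seed: 1
```

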