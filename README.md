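# modsplice

Modular modeling of genetic variant effects on splicing. `modsplice`
scores SNVs and short indels from standard **VCF + GTF + FASTA** inputs
by composing five small sequence models — donor site, acceptor site,
exon, 5′ intron, 3′ intron — through interpretable linear and logistic
models that predict:

- **ΔΨ / Δlogit(Ψ)** — change in percent-spliced-in (exon skipping),
- **ΔΨ5 / ΔΨ3** — shifts between competing acceptor/donor sites,
- **splicing-efficiency change** — as an allelic log₂ ratio,
- **pathogenicity probability** — for splice-region variants.

It is aimed at computational biologists who want quantitative,
physically interpretable splice-variant scores (rather than a black-box
pathogenicity number) and a pipeline that handles indels, minus-strand
genes, and variants affecting several exons at once.

## The model

Each scoring module is a small neural network whose output *before* the
final sigmoid is the module score `S`. For a variant-exon pair the
reference and alternative regions (exon plus `L_a = L_d = 100` nt of
intronic flank, always in transcript orientation) are cut into five
windows — the 18-nt donor window (5 exonic + 13 intronic nt), the 53-nt
acceptor window (50 intronic + 3 exonic nt), the exon, and the two
flanks — and each module contributes `ΔS = S_alt − S_ref`.

The exon-skipping composition model is linear on the logit scale:

```
Δlogit(Ψ) = β₀ + β₁ ΔS_3'intron + β₂ ΔS_acceptor + β₃ ΔS_exon
          + β₄ ΔS_donor + β₅ ΔS_5'intron
          + β₆ 𝟙(exon ∩ splice-site windows) ΔS_exon
          + β₇ 𝟙(5'intron ∩ donor window) ΔS_5'intron
          + β₈ 𝟙(3'intron ∩ acceptor window) ΔS_3'intron
```

— nine parameters, fitted with a Huber loss; the indicator interactions
keep variants that sit inside two scored windows from being counted
twice. Predictions transform to the natural scale via
`Ψ̂_alt = σ(Δlogit(Ψ) + logit(Ψ_ref))`, `ΔΨ̂ = Ψ̂_alt − Ψ_ref`, with
`Ψ_ref` clipped to `[10⁻⁵, 1 − 10⁻⁵]`. Competing splice sites use
`Δlogit(Ψ₅) = Δlogit(Ψ)₁ − Δlogit(Ψ)₂` for the two candidate exons, and
heterozygotes get exactly half the homozygous effect. Splicing
efficiency reuses the same design with the allelic log-ratio
`log₂((m_o/m_i)/(w_o/w_i))` as response; pathogenicity is a logistic
regression over the same features. Model comparisons use the basic
bootstrap, `P = (1 + #{d*_i ≤ 0}) / (B + 1)` with `B = 999`, and
percentile 95% confidence intervals.

Deletions that span a splice site relocate the site to the deletion
boundary and re-extract the flanks, so an alternative allele always has
the same structure as the reference: one exon of flexible length with
exactly `L_a` and `L_d` intronic nucleotides.

## Worked example

Everything below is generated from seeds — no downloads. We simulate a
mini genome, build the six modules, simulate variant effects from known
coefficients, refit the nine-parameter model, and score a variant:

```python
import numpy as np
from pathlib import Path
from modsplice import (load_genome, load_annotation, build_module_set,
                       fit_effect_model, predict_delta_psi, read_vcf,
                       map_variants_to_exons, apply_variant, module_delta_scores)
from modsplice.synthetic_fixtures import (generate_mini_genome,
                                          generate_variant_truth_set,
                                          scores_from_frame)

work = Path("example"); work.mkdir(exist_ok=True)
mini = generate_mini_genome(work, n_genes=12, exons_per_gene=3, seed=0)
genome = load_genome(mini.fasta_path)
annotation = load_annotation(mini.gtf_path)

modules = build_module_set(seed=0)
true_beta = np.array([0.1, -0.8, -1.2, -1.0, -1.5, -0.9, 0.5, 0.6, 0.4])
truth = generate_variant_truth_set(genome, annotation, modules, work,
                                   n_variants=300, true_beta=true_beta,
                                   noise_sd=0.0, seed=1)

model = fit_effect_model(scores_from_frame(truth.table),
                         truth.table["delta_logit_psi"].to_numpy())
print("true beta:  ", np.round(true_beta, 4))
print("fitted beta:", np.round(model.coef, 4))

row = truth.table.loc[truth.table["dS_donor"].abs().idxmax()]
variant = next(v for v in read_vcf(truth.vcf_path) if v.id == row["variant_id"])
pair = next(p for p in map_variants_to_exons([variant], annotation)
            if p.exon.exon_id == row["exon_id"])
pair = apply_variant(genome, pair.exon, pair.variant)
scores = module_delta_scores(pair, modules, exon_head="exon5p")
dlogit, dpsi = predict_delta_psi(model, scores, psi_ref=0.8)
```

Output:

```
true beta:   [ 0.1 -0.8 -1.2 -1.  -1.5 -0.9  0.5  0.6  0.4]
fitted beta: [ 0.1 -0.8 -1.2 -1.  -1.5 -0.9  0.5  0.6  0.4]
variant chrS:4300 C>CTTC on exon g8.e23 (psi_ref = 0.8)
  dS_donor = +1.312  dS_exon = +0.000  ind_intron5p_donor = 1
  delta_logit_psi = -1.866  ->  delta_psi = -0.418
```

The noise-free refit recovers the generating coefficients exactly (the
robust fit is unbiased when its model is correct), and a 3-nt insertion
just inside the donor-side intron of exon `g8.e23` shifts the donor
score by +1.31, which the composition model converts into a predicted
drop of 0.42 in exon inclusion at a reference Ψ of 0.8.

The same pipeline runs from the shell:

```bash
modsplice make-fixtures --out fx --seed 0
modsplice train-modules --fasta fx/mini_genome.fa --gtf fx/mini_genome.gtf \
    --mpra fx/mpra_labels.tsv.gz --out weights --seed 0
modsplice score --fasta fx/mini_genome.fa --gtf fx/mini_genome.gtf \
    --vcf variants.vcf --modules weights --out predictions.tsv
```

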