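# hspcmeth

Targeted DNA-methylation quantification of hematopoietic stem and
progenitor cells (HSPCs).

Monitoring HSPCs — conventionally done by flow cytometry of the CD34
surface marker — matters for stem-cell mobilization, apheresis quality
control, and transplant assessment, but flow cytometry needs fresh cells.
Methylation at a handful of cell-type-specific CpG sites provides an
epigenetic alternative that also works on frozen samples and dried blood
spots. This package implements that pipeline end to end for people working
with β-value matrices (Illumina 450k-style exports) and targeted
bisulfite-pyrosequencing measurements:

1. **Marker selection** — find CpGs that discriminate a target cell
   population by (i) a large difference of group-mean β and (ii) low
   within-group variation, scalarized as
   `score = |Δmean| − w · max(sd_target, sd_rest)`.
2. **Dilution-series calibration** — ordinary least squares of a known
   CD34⁺ fraction (flow cytometry, %) on the β values of a small marker
   panel: `fraction = β₀ + Σ_c β_c · meth_c`, fitted per sample source
   (mobilized peripheral blood vs cord blood) and applied to new samples
   with clamping to [0, 100] (the unclamped value is always retained).
3. **NNLS deconvolution** — estimate the composition over HSPC subsets
   (HSC, LMPP, CMP) and mature leukocytes by non-negative least squares
   `x* = argmin_{x≥0} ‖Ax − b‖₂`, where A is a reference atlas of mean β
   per cell type at each panel CpG and b the sample's panel β vector.

A synthetic-data module generates reference profiles with planted markers,
linear mixtures with technical noise, dilution series, and leukemia-like
cohorts with blast-count covariates, so the whole pipeline is testable
without any external download. The packaged marker panels (`hspc3`: STK17A,
MYO1D, SP140; `subset6`: HLF, STK17A, BMF, FTO, TESC, MYO1D) are included
as `builtin_panel(...)`.

The three stages are scikit-learn-style estimators (`MarkerSelector`,
`DilutionCalibrator`, `NNLSDeconvolver`) and compose with sklearn
pipelines; plain functions (`group_stats`, `fit_dilution_model`,
`deconvolve_sample`, …) wrap them for scripting, and a `hspcmeth` CLI binds
every stage.

## Worked example

```python
import hspcmeth as h

# synthetic reference study: 3 HSPC subsets + 3 leukocyte groups,
# 3 hyper- and 3 hypomethylated markers planted per cell type
spec = h.SyntheticSpec(
    n_cell_types=6,
    cell_type_names=["HSC", "LMPP", "CMP", "granulocyte", "CD4T", "Bcell"],
    n_background_cpgs=200, markers_per_type=(3, 3),
    marker_delta=0.6, within_type_sd=0.02, samples_per_type=5, seed=7,
)
beta, ann, truth = h.make_reference_profiles(spec)

# subset-specific marker selection (3 hypo + 3 hyper per subset)
panels = h.select_subset_markers(beta, ann, ["HSC", "LMPP", "CMP"])
print("HSC markers:", list(panels["HSC"].index))

# reference atlas over the 18 selected CpGs, leukocytes pooled equally
marker_ids = [c for s in panels.values() for c in s.index]
atlas = h.build_reference(
    beta, ann, ["HSC", "LMPP", "CMP", "leukocytes"], marker_ids,
    leukocyte_groups=["granulocyte", "CD4T", "Bcell"],
)

# deconvolve a noisy mixture with true composition 10/15/20/55 %
b = h.simulate_mixture(atlas, [0.10, 0.15, 0.20, 0.55], noise_sd=0.02, seed=1)
res = h.deconvolve_sample(atlas, b, normalize=True, sample_id="mix1")
print("estimated fractions:", res.fractions.round(3).to_dict())
print("residual norm: %.4f" % res.residual_norm)
```

prints

```
HSC markers: ['mk0005_HSC_hypo', 'mk0004_HSC_hypo', 'mk0006_HSC_hypo',
              'mk0001_HSC_hyper', 'mk0003_HSC_hyper', 'mk0002_HSC_hyper']
estimated fractions: {'HSC': 0.094, 'LMPP': 0.154, 'CMP': 0.212, 'leukocytes': 0.54}
residual norm: 0.0444
```

The selector recovers exactly the six CpGs planted for HSCs, and the NNLS
estimate lands within ~1 percentage point of the true 10/15/20/55
composition at β-noise sd 0.02; the residual norm is the remaining
least-squares misfit of the 18-CpG panel.

The same flow is available from the shell:

```bash
hspcmeth simulate reference --seed 7 --out-prefix ref
hspcmeth select --beta ref_beta.tsv --annotations ref_annotations.tsv \
    --target HSC --direction hyper --top 3 --out candidates.tsv
```

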