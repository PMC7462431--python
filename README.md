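# graphfc

Connectome-informed graph smoothing of source-space EEG functional
connectivity, with the statistical machinery to validate it.

## The problem

EEG functional connectivity (FC) computed between source-reconstructed
regional time courses is contaminated by volume conduction: fields spread
instantaneously through the head, producing spurious zero-lag correlations
that decay with the Euclidean distance (ED) between regions. Genuine
coupling, in contrast, is mediated largely by white-matter structural
connectivity (SC). Both effects depend on distance, which makes them hard
to disentangle — but SC carries structure that distance cannot mimic (e.g.
strong callosal connections between distant homotopic regions).

`graphfc` implements a simple structure-informed augmentation: each ROI's
signal is smoothed with its structurally connected neighbors,

    x̂ᵢ(t) = xᵢ(t) + G Σⱼ cᵢⱼ xⱼ(t),        i.e.  x̂ = (I + G·C) x,

where C is a graph derived from the structural connectome and G ≥ 0 is the
filter weight. Around that one-line operator the package provides everything
needed to judge whether it helps: distance-dependent consensus connectomes,
filter-graph variants (SC, dense exp(−k·ED), SC-masked ED, density-matched
ED, degree-preserving nulls), search information, power-envelope /
(imaginary-)coherence FC, a stepwise structure–function GLM with
distance-matched SC⁺/SC⁻ comparisons, fit-vs-G curves against a reference
FC with signed-rank variant comparisons, white-noise controls, repeated
Louvain community matrices over a (γ, G) grid — and a fully synthetic cohort
generator with known leakage-free ground truth, so the entire pipeline is
testable without any acquisition data.

Audience: EEG/MEG researchers working in source space with an interest in
structure–function coupling, and methodologists who need a controlled
sandbox for leakage-correction ideas.

## Worked example

```python
import graphfc as g

# a self-contained synthetic study: 68 ROIs, 18 subjects with 2-5
# artifact-free intervals each, SC-coupled band-limited sources passed
# through a distance-dependent leakage kernel, plus an independent
# leakage-free reference FC (30 subjects)
study = g.make_study(seed=1)

cons = g.consensus_sc(study.subject_scs, study.parcellation)
print(f"consensus density {cons.density_overall:.1%} "
      f"({cons.density_intra:.1%} intra, {cons.density_inter:.1%} inter)")

graph = g.build_filter_graph("ed_match", sc=cons, parcellation=study.parcellation)
fcs = g.filtered_fc_study(study.epochs_by_subject, graph,
                          [0.0, 0.05, 0.1, 0.2, 0.4, 1.0], study.band)
curve = g.fit_curve(fcs, study.reference_fc, variant="ed_match")
print(curve.mean_z_by_G().round(3).to_dict())
```

prints

```
consensus density 17.7% (28.2% intra, 7.6% inter)
{0.0: 0.935, 0.05: 0.963, 0.1: 0.968, 0.2: 0.953, 0.4: 0.912, 1.0: 0.848}
```

Reading: without filtering (G = 0) the subjects' envelope-FC matrices fit
the leakage-free reference at a mean Fisher-z of 0.935; smoothing on the
SC-masked-ED graph raises the fit to 0.968 at G = 0.1 before over-smoothing
sets in at large G. The same run shows the improvement is significant within
subjects (Wilcoxon signed-rank on per-subject maximum fits vs baseline,
p ≈ 8·10⁻⁶) while the dense-ED graph — same distance profile, no SC mask —
achieves no significant improvement: the gain comes from the connectome's
support, not from distance alone.

A command-line interface mirrors the pipeline (`graphfc simulate | graphs |
si | filter | fc | glm | fitcurve | communities`); every subcommand takes
`--config`, `--out`, `--seed`, `--log-level` and operates on the study
directory written by `simulate`. See `docs/methods.md` for the model,
parameter conventions, and what the synthetic world does and does not
emulate.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end synthetic analysis from scratch:
generates the default cohort and its independent reference at the given
seed, builds the consensus connectome and filter graphs, computes
fit-vs-G curves for the SC-masked-ED and dense-ED variants with signed-rank
comparisons, and runs the community-agreement sweep at the resolution
yielding about five communities, printing each stage's summary and writing
the results JSON to `--out`. One run takes about two minutes.
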