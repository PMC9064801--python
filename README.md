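# viroconverge

Event-anchored analysis of longitudinal gut-virome cohorts: does beta
diversity between case infants *converge* in the days before a clinical
event?

Preterm infants who develop necrotizing enterocolitis (NEC) — a sudden
necroinflammatory intestinal disease — may carry viral signatures in the gut
before onset. Given stool-derived viral contig counts sampled longitudinally
from matched case/control infants, this package re-times every sample as
days-before-event (controls borrow their matched case's onset day), slides
7-day windows back from the event, and asks whether between-case
dissimilarity drops below between-control dissimilarity as onset approaches.
It then identifies the contigs responsible, follows their prevalence and
abundance trajectories, and tests virus–bacteria associations on a matched
16S genus table.

The pipeline, for samples `x` with RPK abundance
`RPK = (79000 / total reads) x mapped reads / (contig kb)` (values < 0.5
floored to 0):

* **alpha/beta diversity** — richness, Shannon `H = -Σ p_i ln p_i`; Sorensen
  `1 - 2|A∩B| / (|A|+|B|)`, weighted Bray–Curtis `Σ|x−y| / Σ(x+y)`,
  Hellinger on `ln(1+RPK)`; weighted/unweighted UniFrac on a genus tree
* **cohort structure** — within- vs between-infant dissimilarity
  (Mann–Whitney), PCoA, PERMANOVA with a continuous covariate
  (postmenstrual age)
* **convergence** — per-window between-case vs between-control Mann–Whitney
  on matched sample pairs (±3.5 d)
* **discriminant screen** — LDA-effect-size selection of contigs associated
  with the 10 d before the event vs the 11–46 d antecedent period
  (10% prevalence gate, Kruskal–Wallis α = 0.05, log10 LDA score ≥ 2)
* **trajectories** — prevalence/abundance in 5 d blocks, Friedman + Dunn,
  per-contig regression slopes
* **interactions** — per (contig, genus) random-intercept mixed models,
  significant at P < 0.05 and BH q < 0.25

Because the cohorts such analyses run on are not redistributable, the
package includes a first-class synthetic-cohort generator
(`viroconverge simulate`) with planted, labelled effects — a programmable
pre-event convergence signature, early-period contigs, control-side
age-ramping contigs, and signed contig–genus couplings — so every stage is
verifiable against known truth. See `docs/methods.md` for the model.

## Worked example

```python
import viroconverge as vc

# a 9-case / 14-control cohort, ~140 samples, 2,000 contigs
meta, viral, catalog, bacteria, tree, truth = vc.generate_cohort(
    vc.SyntheticParams(seed=1)
)
abundance = vc.rpk_normalize(viral, catalog, meta.samples)

# individuality: viromes are self-similar over time, distinct across infants
bc = vc.bray_curtis(abundance)
med_within, med_between, test = vc.within_between(bc, meta.samples)
print(f"median Bray-Curtis within {med_within:.3f} vs between {med_between:.3f}")

# convergence: Sorensen in 7 d windows (2 d steps) before the event
soer = vc.sorensen(vc.presence_matrix(abundance))
anchored = vc.anchor(meta)
pairs = vc.pair_samples(anchored, meta)
series = vc.convergence_series(
    soer, vc.build_windows(vc.WindowSpec(7, 2, 25), anchored), pairs
)
for w in series.windows[:3]:
    print(f"{w.label}: case {w.test.extra['case_median']:.3f} "
          f"control {w.test.extra['control_median']:.3f} p={w.test.p_value:.2g}")

# which contigs drive it?
feats = vc.lefse_screen(abundance, anchored, vc.LefseConfig(seed=1))
late = {f.contig_id for f in feats if f.assigned_class == "late"}
sig = set(truth.signature_contigs)
print(f"recovered {len(late & sig)}/{len(sig)} planted signature contigs")
```

prints

```
median Bray-Curtis within 0.483 vs between 0.982
7-0d: case 0.807 control 0.891 p=4.1e-54
9-2d: case 0.866 control 0.891 p=3e-06
11-4d: case 0.880 control 0.899 p=0.024
recovered 127/137 planted signature contigs
```

Between-case Sorensen dissimilarity sits well below between-control in every
window overlapping the planted 10-day signature window — the convergence
signal — and the discriminant screen recovers 93% of the contigs that were
planted to cause it.

The same analyses are exposed as a CLI
(`viroconverge simulate | normalize | distance | converge | lefse | unifrac | run`);
`viroconverge run --config pipeline.yaml` executes all eight stages and
writes plain-TSV outputs plus a hash manifest (identical config + seed gives
identical hashes).

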