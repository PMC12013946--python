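# dcquant

Quantitative assays for X-chromosome dosage compensation in *C. elegans*
nuclei: single-nucleus image quantification of chromosome-territory
compaction and radial position, the X-vs-autosome derepression statistic on
differential-expression tables, and progeny-viability contingency
statistics — together with a synthetic-data generator that stands in for
microscopy stacks and RNA-seq counts with known ground truth.

## Who this is for

In hermaphrodite *C. elegans*, a condensin-containing dosage compensation
complex binds both X chromosomes, halves their transcription, compacts the
X territory, and keeps it near the nuclear periphery. Perturbing that
machinery (degron depletion, pathway mutants) is read out through a small
set of quantitative assays, which this package implements as a tested,
scriptable pipeline:

- **volume fraction** `v` — chromosome-paint voxels inside the nuclear mask
  over nuclear-mask voxels (compaction proxy);
- **three-zone assay** — the fraction of the signal in each of three
  concentric, equal-area elliptical zones of a mid-nucleus slice
  (radial-position readout);
- **line-scan enrichment** `E` — peak / minimum intensity along a line
  through the nucleus crossing the enriched region;
- **intensity ratio** `I` — mean nuclear intensity / mean background
  intensity;
- **X derepression** `d = median(log2FC_X) − median(log2FC_autosome)`, with
  fold equivalent `2^d` and a two-sided Wilcoxon rank-sum comparison of the
  two log2FC sets; binned log2FC profiles along chromosome coordinates;
- **viability statistics** — pooled dead/live 2×2 tables with Fisher's
  exact test, chi-square on/off-auxin comparisons, survival ratios, and
  brood viabilities.

See `docs/methods.md` for conventions, noise models, and limitations.

## Worked example

Simulate a two-condition RNA-seq experiment with a known uniform 0.435
log2-unit shift on X-linked genes, estimate fold changes internally, and
recover the derepression statistic:

```python
import dcquant
from dcquant.expression import log2_fold_changes, derepression

counts, genes, truth = dcquant.generate_count_matrix(
    dcquant.CountSimParams(d_true=0.435, seed=1)
)
table = log2_fold_changes(counts, truth["groups"], gene_info=genes)
print(derepression(table).summary())
```

```
X derepression d = 0.434 (1.35-fold), median X = 0.377 (n=2800),
median autosome = -0.057 (n=17200), Wilcoxon W = 45479948.0, p = 0
```

The estimate recovers the simulated shift (0.434 vs 0.435); its fold
equivalent `2^0.434 ≈ 1.35` means X-linked genes are expressed ~1.35× higher
in the treatment condition, and the rank-sum test confirms the X and
autosomal log2FC distributions differ (p below double precision).

Quantify one synthetic wild-type-like nucleus end to end:

```python
dapi, sig, truth = dcquant.generate_nucleus_stack(dcquant.preset("wt-like", seed=1))
q = dcquant.quantify_nucleus(dapi, sig)
print(q.volume_fraction, q.zone_fractions, q.enrichment_ratio, q.intensity_ratio)
```

```
v=0.1250  zones=(0.812, 0.188, 0.0)  E=4.23  I=13.74  qc=True
```

The territory occupies 12.5% of the nuclear volume (the preset's ground
truth), sits mostly in the central+intermediate zones at the preset's
radial position, shows ~4× line-scan enrichment (the simulated stain
contrast), and the nucleus is 13.7× brighter than background.

The same operations are available from the shell:

```bash
dcquant simulate-image --preset wt-like --seed 1 --out-prefix scratch/n01
dcquant quantify scratch/ --out scratch/results.tsv
dcquant simulate-counts --d-true 0.435 --seed 1 --out scratch/counts.tsv
dcquant derepress --dge my_dge_table.tsv
dcquant viability --table counts.csv --ref N2
```

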