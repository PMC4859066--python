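# macckit

Chromatin accessibility from MNase titration series.

Micrococcal nuclease (MNase) digestion is the workhorse assay for mapping
nucleosomes, but the apparent occupancy it reports depends strongly on how
deep the digestion is: accessible chromatin is released preferentially under
light digestion and destroyed by over-digestion, while compact chromatin
needs high enzyme levels before it yields mononucleosomal fragments.
`macckit` turns this digestion dependence from a nuisance into a
measurement. Given paired-end fragment libraries from a titration of
increasing MNase amounts (e.g. 1.5, 6.25, 25 and 100 U), it scores every
genomic bin with the **MACC** statistic (MNase accessibility):

```
MACC_i = slope of OLS fit of  y_ij  on  x_j = −ln c_j ,   j = 1..k
```

where `y_ij` is the normalized fragment frequency of bin *i* at MNase
amount `c_j` (per million mapped reads, scaled by genome size / 100 Mb).
Positive MACC marks accessible chromatin (yield falls with enzyme amount,
"scenario 1"); negative MACC marks inaccessible chromatin ("scenario 2").
Computed on whole-chromatin digests the score is called **c-MACC**; on
histone-ChIP digests, **h-MACC**. Comparing the two separates histone from
non-histone DNA protection: bins with high c-MACC but near-zero h-MACC
(**group 1**) carry non-histone-protein footprints, bins high in both
(**group 2**) carry accessible ("fragile") nucleosomes.

The package is aimed at epigenomics groups running MNase titration
experiments (fly, mouse or human scale) and covers the full analysis:

- fragment input (BAM / BEDPE / BED), insert-size filtering (50–500 bp),
  anomalous-position removal (Z > 7), midpoint binning (300/500-bp bins)
  and per-million + genome-size normalization;
- MACC fitting with Pearson or Mann–Kendall significance weighting,
  LOWESS GC-bias correction (optionally stratified by CpG islands) and
  median shifting;
- two-state Gaussian-HMM segmentation into accessible/inaccessible
  domains with a within-chromosome shuffled null;
- strict local-maximum peak calling, group-1/group-2 classification
  (80/10/90 percentiles of positive scores), NHP-site derivation from
  ChIP Z-scores, randomized overlap statistics and region enrichment;
- site-centred average profiles (TSS, peaks, enhancers) and UPGMA
  clustering of per-sample profiles (distance 1 − Pearson r);
- a fully ground-truthed synthetic titration simulator, so every stage
  is testable without external data.

## Worked example

Simulate a ground-truthed titration (5,000 × 300-bp bins, three pools,
depth 50 fragments/bin/point) and run the full pipeline:

```bash
$ macckit simulate --n-bins 5000 --depth 50 --seed 7 --out demo
fixture written to demo (3,286,573 fragments)

$ macckit run demo/config.yaml
accessible coverage: 0.7682
inaccessible coverage: 0.2318
accessible median run length: 68.0 bins (shuffled: 2.0)
inaccessible median run length: 25.0 bins (shuffled: 1.0)
group counts: {'group1': 139, 'group2': 223, 'none': 4638}
```

Reading the output: the two-state HMM assigns 77% / 23% of defined bins to
the accessible / inaccessible state on this synthetic genome, and the
observed state stretches (median 68 and 25 bins) are far longer than on the
shuffled profile (2 and 1 bins) — accessibility is organized in domains,
not scattered bin by bin. 139 bins show the group-1 signature (high c-MACC,
near-zero h-MACC: non-histone protection; the simulator planted ~150 such
loci) and 223 bins the group-2 signature (high c-MACC and h-MACC: fragile
nucleosomes). Artifacts land in `demo/results/`: normalized per-point
tracks, `c-MACC.bedgraph` / `h-MACC.bedgraph`, `hmm_states.bed`,
`peaks.bed`, `groups.bed`, a threshold summary TSV and a provenance record
(`run_info.json`).

The same steps are available as library calls (`read_fragments`,
`fit_macc`, `gc_correct`, `median_shift`, `fit_two_state_hmm`,
`assign_groups`, `site_profile`, `cluster_profiles`, ...); see
`docs/methods.md` for the model details and parameter guidance.

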