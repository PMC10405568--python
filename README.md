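# sisrna

Analysis of **circular stable intronic sequence RNAs (sisRNAs)** from total
RNA-Seq junction evidence.

Most excised introns are debranched by Dbr1 and degraded within minutes, but
some persist as circular molecules: **stable lariats**, which keep the 2′-5′
branch junction so their circle closes at an internal branch point (BP), and
**full-length intronic circles**, whose junction joins the 5′ splice site to
the 3′ splice site (3′-5′ linkage). Back-splice callers (CIRCexplorer2, DCC,
circRNA_Finder, CIRIquant) report the junction-spanning reads that evidence
these molecules, but their raw calls are noisy: the reverse transcriptase
stutters over the 2′-5′ bond, scattering the apparent 3′ end of the same
lariat over nearby positions. `sisrna` is the post-caller layer: it turns
per-sample junction tables into a clean, classified sisRNA catalogue and runs
the downstream feature and cohort analyses, for transcriptomics researchers
studying intron-derived circular RNAs in tissues, cell fractions, or
clinically annotated cohorts.

## What it computes

- **Intron universe** — per gene, isoform introns are union-merged and
  positions overlapping any exon are subtracted (`kept_blocks`), giving
  unique non-exon-overlapping introns; host-candidate introns have a span of
  100–10 000 bp. The host of a circular interval is the *shortest intron
  fully containing it*, with a 5′-concordance flag (|Δ5′SS| ≤ 10 bp).
- **Junction clustering** — calls are filtered (no mitochondrial calls, no
  non-coding host genes, circle length 30–10 000 bp), collapsed per
  (host intron, 5′SS) with the max-read end as representative, required in
  ≥ 2 samples, and classified: *intronic circle* iff the representative end
  sits at the intron's 3′SS (± `tol_3ss`), else *stable lariat*.
- **Branch-point features** — external BP map assignment (max support,
  ties to the 3′SS-proximal position), 3′ tail length (BP→3′SS distance,
  tails ≤ 1 bp discarded), caller-vs-map concordance, BP nucleotide usage.
- **Sequence context** — strand-aware windows anchored at the 5′SS, BP, or
  3′SS; per-position nucleotide frequencies and information content
  `bits(i) = Σ_n p_n(i) log2(p_n(i)/q_n)` (Kullback–Leibler divergence
  against a uniform background); IUPAC motif scanning (e.g. `AYAUUAUUAAU`)
  over 101-nt BP-centred windows with per-hit offsets.
- **Tracks** — read-depth from aligned blocks (linearly spliced reads whose
  gap spans the intron are removed), phyloP conservation, whole-intron means
  (10 bp splice-site trims), anchored positional profiles, and per-offset
  group contrasts `log FC = log2((a1 + 1e-6)/(a2 + 1e-6))`.
- **Expression & enrichment** — RPM (`reads × 1e6 / library size`), FPKM
  (`reads × 1e9 / (length × library size)`), relative intron expression
  `(intron FPKM + 1e-6)/(gene FPKM + 1e-6)`, RNase-R enrichment
  (treated/control RPM ratio > 1) with a two-sided Fisher exact test on
  junction type × enrichment, and Spearman junction–intron coupling.
- **Cohort statistics** — tissue specificity (mean RPM per tissue, top-decile
  contribution, intronic-circle fraction), nuclear/cytoplasmic localization,
  pairwise risk-class differential expression (two-sided Wilcoxon rank-sum,
  Benjamini–Hochberg per class pair, q < 0.1), and Kaplan–Meier /
  log-rank survival with median-expression dichotomization (strictly-greater
  high group, so a 0 median splits zero vs nonzero).
- **Synthetic data** — a ground-truthed generator (`sisrna.simulate`) that
  emits a complete input bundle (genome FASTA, GTF, per-sample junction BEDs
  with RT jitter, BP map, bedGraph tracks, count matrices, metadata with risk
  classes and survival) for end-to-end validation.

## Worked example

```python
from sisrna.pipeline import RunConfig, run_pipeline
from sisrna.simulate import SimConfig, simulate

bundle = simulate(SimConfig(seed=7), "example/sim")
result = run_pipeline(RunConfig(
    annotation=bundle.paths["gtf"],
    junction_dir=bundle.paths["junction_dir"],
    metadata=bundle.paths["metadata"],
    genome=bundle.paths["genome"],
    bp_map=bundle.paths["bp_map"],
    conservation=bundle.paths["conservation"],
    outdir="example/run",
))

n = len(result.clusters)
lariats = sum(c.cls == "stable_lariat" for c in result.clusters)
print(f"sisRNA clusters: {n} ({lariats} stable lariats, {n - lariats} intronic circles)")
conc = result.bp_concordance
print(f"caller vs map BP distance: median {conc['median']:.0f} bp, "
      f"mean {conc['mean']:.1f} bp, {100 * conc['frac_below']:.0f}% < 20 bp (n={conc['n']})")
print(f"BP-region conservation log2 FC > 1 at "
      f"{100 * result.conservation_logfc.exceedance_fraction:.1f}% of offsets")
print(f"survival (total RPM, median cut {result.survival.cutoff:.2f}): "
      f"log-rank p = {result.survival.p:.2e}")
```

prints

```
sisRNA clusters: 98 (58 stable lariats, 40 intronic circles)
caller vs map BP distance: median 0 bp, mean 3.6 bp, 96% < 20 bp (n=50)
BP-region conservation log2 FC > 1 at 100.0% of offsets
survival (total RPM, median cut 11.64): log-rank p = 5.86e-11
```

98 clusters pass the filters, split into the two circular classes; the
caller-derived 3′ ends agree with the external BP map at a median distance
of 0 bp; conservation around stable-lariat branch points exceeds the
non-host background by more than two-fold at all offsets (the generator
plants a +1 phyloP elevation in a ±50 bp BP window); and patients with
below-median total sisRNA expression progress faster (the planted hazard
ratio is 2).

The same stages are available from the shell — `sisrna simulate`,
`sisrna build-introns`, `sisrna collapse`, `sisrna bp-features`,
`sisrna scan-motif`, `sisrna expression`, `sisrna cohort`,
`sisrna survival`, `sisrna run`, `sisrna truth-compare`; see
`sisrna --help`. Every output table is a headered TSV; `run` also writes a
`manifest.json` with per-stage parameters and conserved filter counts.

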