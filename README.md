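# strainscope

Strain-level chemical and genomic heterogeneity analysis for bacterial
natural-product collections.

## The problem

Strain-prioritization ("dereplication") strategies discard presumed-redundant
strains of a species before screening for natural products. But strains that
are indistinguishable by phylogeny and genome mining can differ sharply in
what they actually produce — in yield, in structural diversity, and in which
novel compounds appear at all. Quantifying that heterogeneity requires a
pipeline that spans both sides: untargeted MS/MS chemistry (molecular
networking, diagnostic-fragment classification, exact-mass formula
assignment, semi-quantification against a reference strain) and comparative
genomics (biosynthetic-gene-cluster presence/absence across the collection,
mutation profiles of conserved clusters).

`strainscope` implements that pipeline as a tested library plus CLI, with a
synthetic-data generator so every stage is exercisable — and checkable
against planted ground truth — without raw instrument data. It ships the
33-compound bagremycin/bagrelactone table from a *Streptomyces lunaelactis*
moonmilk-isolate collection as a packaged fixture.

## The core computations

- **Modified cosine** between MS/MS spectra *a*, *b*: fragments are matched
  one-to-one within a tolerance, either directly or offset by the precursor
  mass difference Δ = *m*ₐ − *m*ᵦ; with per-spectrum L2-normalized weights
  *wᵢ* ∝ √Iᵢ the score is Σ *wᵢwⱼ* over matched pairs. Nodes (consensus
  spectra, minimum cluster size 4) are linked at cosine ≥ 0.7; connected
  components are the "constellations" (structural families).
- **Diagnostic tag fragments** assign spectra to compound groups
  (*m/z* 121.06, 255.04, 178.05 for bagremycin groups 1–3), with
  neutral-loss detection at precursor − (tag − proton).
- **Exact-mass tools**: monoisotopic masses, the two ion-formula conventions
  ([M+H]⁺ of a neutral vs an electron-corrected cation), Δm in ppm, RDBE,
  and exhaustive CHNOS formula decomposition within ppm tolerance.
- **Relative abundance**: RA(s, c) = 100 · A(s, c)/A(ref, c) from EIC peak
  areas, the reference strain fixed to 100%.
- **Pan-BGC statistics**: union/core/strain-specific partition of a binary
  strains × BGC-family matrix, families absent from the type strain, and
  families unique to one strain ("grape" network export).
- **Mutation profiling**: global affine-gap CDS alignment, codon-level
  classification into silent / non-silent / in-frame-deletion events under
  the bacterial codon table, with distinct-vs-per-strain bookkeeping.

## Worked example

```python
from strainscope.formula import Formula, ion_mz, ppm_error, PROTONATED, decompose_mass

f = Formula.parse("C20H20N2O6S")          # bagremycin C, neutral molecule
theo = ion_mz(f, PROTONATED)              # [M+H]+
print(f"[M+H]+ of C20H20N2O6S = {theo:.4f}")
print(f"ppm vs printed 417.1115 = {ppm_error(417.1115, theo):+.2f}")
for c in decompose_mass(417.1115, PROTONATED, tol_ppm=3.0)[:3]:
    print(f"{c.formula}  mz={c.theoretical_mz:.4f}  ppm={c.ppm:+.2f}  rdbe={c.rdbe}")
```

prints

```
[M+H]+ of C20H20N2O6S = 417.1115
ppm vs printed 417.1115 = +0.04
C20H20N2O6S  mz=417.1115  ppm=+0.04  rdbe=12.0
C13H22NO14  mz=417.1113  ppm=+0.47  rdbe=3.5
C19H22N5S3  mz=417.1110  ppm=+1.17  rdbe=11.5
```

i.e. the sulfur-bearing bagremycin C formula is the top-ranked decomposition
of its own published ion mass, 0.04 ppm from the printed value. The
runner-up formulas are mass-compatible but chemically implausible (RDBE 3.5
for an aromatic natural product, or five nitrogens with three sulfurs).

The full synthetic pipeline runs from the shell:

```bash
strainscope run --seed 1 --outdir out/
strainscope panbgc out/bgc_matrix.tsv --type-strain S01
```

writing per-strain MGFs, the molecular network (GraphML + node/edge TSV),
group calls, relative-abundance tables, dendrograms and a JSON report.

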