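# tcrprofile

Toolkit for evaluating T-cell receptor (TCR) repertoire profiling from
short-read RNA-seq — for immunogenomics researchers who want to know when
whole-transcriptome data (single-cell or bulk) can stand in for targeted
amplicon repertoire sequencing.

The core difficulty is sampling: only ~1e-5 (TCRα) to ~2e-5 (TCRβ) of
transcriptome reads cover a CDR3 junction, so a 150M-read bulk library
yields only ~10³ CDR3 reads, and a Fluidigm-scale single-cell experiment
profiles only ~10² cells.  Whether that is enough depends on the
repertoire: clonally *expanded* repertoires (top clone frequencies of
several percent) are recovered faithfully, while *diverse* naive-like
repertoires (≥ 10⁴ clones, max frequency ~10⁻³) are hopelessly
under-sampled.  `tcrprofile` makes that argument quantitative with an
explicit simulation and analysis chain:

- **Identity** — a clonotype is V-CDR3-J at the gene level
  (identical-sequence TRAV pairs merged, alleles stripped, productive
  junctions only); a clone is an (α, β) pair.
- **Consensus calling** — a clonotype is kept when ≥ 2 of k callers agree
  on CDR3 + J with a non-empty V-set intersection; under independent
  per-caller dropout d, 2-of-3 consensus retains 1 − [d³ + 3d²(1−d)].
- **Abundance** — a read with N ambiguous V annotations contributes 1/N
  of a read to each candidate (weight conservation exact); clone-level
  abundance counts cells, biallelic cells counting once per allele.
- **Detection power** — P(clone of frequency f seen among n cells)
  = 1 − (1−f)ⁿ; joint top-k power by inclusion-exclusion or Monte-Carlo.
- **Signatures** — RPKM-based QC and DE (presence ≥ 50% in the higher
  group, FC ≥ 1.5, two-sided t-test on log2(RPKM+1), p ≤ 0.05), with the
  clone signature as the direction-consistent intersection of four
  comparisons ranked by mean fold change.

See `docs/methods.md` for the full model description and the design
choices behind the simulator defaults.

## Worked example

```python
from tcrprofile import (CellCallSet, clonal_frequencies, min_cells, p_detect)
from tcrprofile.experiments import clone_census_cells

# 89 cells with a TCR called: clones of 13, 12, 6, 5, 3, 3, 2, 2, 2, 2
# cells plus 39 singletons
cells = clone_census_cells()
vec = clonal_frequencies(cells, level="clone")
print([vec.percent(k) for k, _ in vec.ranked()[:3]])
print(round(p_detect(0.03, 100), 5), min_cells(0.002, 0.95))
```

prints

```
[14.6, 13.5, 6.7]
0.95245 1497
```

i.e. the two dominant clones sit at 14.6% and 13.5% clonal abundance, a
3% clone is seen almost surely (p = 0.95245) among 100 cells, while a
0.2% clone needs 1497 cells to be sampled with 95% probability — the
quantitative version of "~100 cells see only the top clones".

The numbered drivers under `analysis/` run the full evaluation and write
their tables to `results/`:

```sh
python analysis/01_simulate_repertoires.py 0    # repertoires + observation
python analysis/02_consensus_calling.py 0       # consensus recovery vs closed form
python analysis/03_abundance_quantification.py 0
python analysis/04_platform_comparison.py 0     # expanded-vs-diverse contrast
python analysis/05_sampling_power.py 0
python analysis/06_expression_signature.py 0
```

A thin CLI mirrors the library (`tcrprofile simulate|consensus|quantify|
compare|power|signature`).

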