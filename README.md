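# scmosaic

Single-cell analysis of **mosaic structural variants (mSVs)** — somatic
rearrangements present in only a subset of a tissue's cells — built around
template-strand (Watson/Crick) sequencing of single cells, with companion
modules for nucleosome-occupancy cell typing and expression-based validation.

## The science

Strand-aware single-cell sequencing preserves which DNA template strand each
homolog inherited at the last division. Binning a cell's reads by strand
yields a per-chromosome **ground state** (WW, WC or CC), and deviations from
it are information-rich:

- a single changepoint consistent with one homolog flipping template
  (WW↔WC or CC↔WC) is a **sister chromatid exchange (SCE)** — the visible
  scar of a repaired double-strand break;
- a WW↔CC jump cannot be produced by one flip and is flagged as a
  candidate mSV;
- within a candidate interval, each SV class (deletion, duplication,
  inversion, inverted duplication, chromosome loss) leaves a **diagnostic
  footprint**: a specific combination of read depth and strand orientation
  given the cell's ground state. Genotyping every cell against these
  footprints yields carriers, a **cell fraction (CF)**, and a
  singleton/subclonal status per event.

Around this core, the package provides the full downstream workflow:
negative-binomial modelling of SCE **hotspots** along the genome and
permutation tests for their co-localization with mSV breakpoints;
PLS-DA/VIP-based **cell typing** from single-cell nucleosome occupancy (NO);
resampling tests for **cell-type enrichment** of mSV subclones;
sliding-window likelihood-ratio tests for **haplotype-specific chromatin
accessibility** changes in *cis* around an mSV; and re-calling of
copy-number alterations in scRNA-seq expression via two-component
**Gaussian-mixture** region scores. Simulators with full ground truth
(planted SCEs, mSV footprints, NO signatures, cis windows, expression
clones) back every statistical claim in the test suite.

## Worked example

Simulate 60 strand-aware cells with a heterozygous deletion planted on
chr1:5.0–12.0 Mb at cell fraction 0.25, then call strand states, SCEs and
the deletion itself:

```python
from scmosaic import (SimConfig, simulate_strand_cells, call_strand_states,
                      detect_sces, genotype_footprints)

config = SimConfig(
    genome=[("chr1", 20_000_000), ("chr2", 20_000_000)],
    n_cells=60, reads_per_cell=40_000.0, sce_rate=0.5,
    msv_events=[("del", "chr1", 5_000_000, 12_000_000, "H1", 0.25)],
    background_noise=0.002, seed=42)
matrix, truth = simulate_strand_cells(config)

segments = call_strand_states(matrix)
sces = detect_sces(segments)
print(f"SCE calls: {len(sces.calls)}  held for review: {len(sces.review)}")

calls = genotype_footprints(matrix, segments,
                            [{"id": "cand_1", "chrom": "chr1",
                              "start": 5_000_000, "end": 12_000_000}])
call = calls[0]
print(f"{call.event_id}: {call.svclass} {call.chrom}:{call.start}-{call.end} "
      f"({call.haplotype})")
print(f"carriers {len(call.carriers)}/{call.n_analyzed} cells, "
      f"CF {call.cf_percent}%, {call.status}")

# carriers whose chromosome also shows an SCE need manual review: a strand
# switch inside the candidate interval mimics an SV footprint
sce_cells = {c.cell for c in sces.calls if c.chrom == call.chrom}
confident = [c for c in call.carriers if c not in sce_cells]
print(f"carriers without a co-occurring {call.chrom} SCE: {len(confident)}")
print(f"truly planted carriers: {len(truth.msv_carriers['msv_0'])}")
```

Output:

```text
SCE calls: 22  held for review: 1
cand_1: del chr1:5000000-12000000 (ambiguous)
carriers 21/60 cells, CF 35.0%, subclonal
carriers without a co-occurring chr1 SCE: 14
truly planted carriers: 15
```

The naive carrier list overestimates the cell fraction because cells with an
SCE on the candidate chromosome present a mixed strand state inside the
interval, which mimics an SV footprint; cross-checking against the SCE
callset recovers 14 of the 15 planted carriers with no false positives (one
true carrier is discarded because it also has a chr1 SCE). The event-level
haplotype is reported as `ambiguous` here because in WC-state chromosomes the
deleted homolog is the Watson template in some cells and the Crick template
in others. See `docs/methods.md` for the underlying models.

## Command line

Every stage is also a CLI command (`scmosaic --help`), and the `pipeline`
command chains them reproducibly:

```yaml
# run.yaml
stages: [simulate_strand, strand_sce, hotspots]
outdir: out
seed: 7
params:
  simulate_strand: {n_cells: 20}
```

```bash
scmosaic pipeline run --config run.yaml
```

A single global seed deterministically derives per-stage seeds; reruns with
the same config produce byte-identical outputs, recorded with SHA-256 hashes
in `out/manifest.json`. Exit codes: 0 ok, 2 configuration error, 3 data or
dependency error.

## Package map

| module | contents |
| --- | --- |
| `scmosaic.genome` | genome model, half-open intervals, bins, BED I/O |
| `scmosaic.simulate` | strand, NO, CRE-haplotype and expression simulators |
| `scmosaic.strand` | strand-state segmentation, SCE calling, footprint genotyping |
| `scmosaic.hotspots` | NB hotspot model, BH calling, overlap permutation tests |
| `scmosaic.celltyping` | NO normalization, two-stage VIP selection, PLS-DA classifier, LOOCV |
| `scmosaic.enrichment` | binomial + resampling subclone composition tests |
| `scmosaic.cis` | sliding windows, haplotype log-ratios, LRT, permutation FDR |
| `scmosaic.cna` | expression normalization, Gaussian-mixture region tests, clone assignment |
| `scmosaic.pipeline` / `scmosaic.cli` | stage orchestration, manifests, CLI |

## Tests and acceptance

```bash
pytest -q                      # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` asserts one documented tolerance per acceptance
area (worked-example arithmetic, NB parameter recovery and BH calibration,
overlap-test null uniformity and planted sensitivity, cell-typing recovery
and LOOCV AUC, enrichment calibration and power, cis-window detection and
null uniformity, CNA re-calling, SCE precision/recall and footprint
genotyping). One known shortfall is left failing on purpose: two-stage VIP
selection recovers ~74% of planted signature genes in the 8-class,
effect-1.0 reference scenario, below the 80% criterion — see
`docs/methods.md` for the structural reason.
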