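# msipcr

Microsatellite-instability (MSI) analysis for non-labeled capillary
electrophoresis, built for molecular-pathology pipelines that run MSI-PCR on
the five-marker mononucleotide panel (BAT-25, BAT-26, NR-21, NR-24, NR-27)
with co-injected 15 bp / 1000 bp alignment markers instead of fluorescent
size standards.

## What it does

MSI is the phenotype of defective DNA mismatch repair (dMMR): somatic length
changes at short tandem repeats, predominantly multi-base deletions at poly-A
loci. The workflow implemented here is the paired tumour/normal comparison
used in clinical screening:

1. **Sizing** — detect band apexes in each lane's electropherogram, verify
   that each alignment marker appears as a single peak with no shoulder, fit
   the log-linear mobility model `size(m) = exp(a + b·m)` exactly through the
   two anchors, and report calibrated sizes. Because both anchors ride the
   same lane, any affine migration distortion cancels.
2. **Calling** — for each marker, a tumour is *unstable* when the major band
   shifts by ≥ 3 bp relative to the paired normal, or when new minor bands
   appear. Bethesda classification: 0 unstable markers → MSS, 1 → MSI-L,
   ≥ 2 → MSI-H.
3. **Two-tier escalation** — markers showing an inconclusive smear on the
   screening gel (10–15 bp resolvability) are re-called from a
   high-resolution gel (1–3 bp); calls conclusive at the screening tier are
   never altered.
4. **LOD** — per-marker limit of detection from a tumour-DNA titration
   (100/50/20/10/7.5/5/2.5%): the smallest fraction with an unbroken run of
   unstable calls from the pure-tumour point down.
5. **Concordance** — MSI-PCR (MSI-H vs MSS+MSI-L) against MMR
   immunohistochemistry dichotomized as any-protein loss (MLH1, MSH2, MSH6,
   PMS2), plus cohort association tables with two-sided Fisher's exact tests
   (Freeman–Halton for 2×k).

Because no public electropherogram data exist for this assay class, the
package includes a first-class simulator (`msipcr.cesim`) that generates
paired lanes with known ground truth: Gaussian bands per allele,
contraction-side stutter ladders, baseline noise, per-lane affine migration
distortion, tumour-fraction mixing, titration series, and cohorts with
configurable MSI-H prevalence and IHC error structure.

## Worked example

```python
from msipcr import (CaseTruth, GelModel, default_panel, simulate_case,
                    run_two_tier)

panel = default_panel()
truth = CaseTruth(
    case_id="demo",
    unstable_markers=frozenset({"BAT-26", "NR-21"}),
    deletion_bp={"BAT-26": 14, "NR-21": 12},
    tumor_fraction=0.35,
)
gel_screen, gel_high = GelModel.screening(), GelModel.highres()
normal, tumor = simulate_case(truth, gel_screen, seed=7)
provider = lambda: simulate_case(truth, gel_high, seed=7)
result = run_two_tier(normal, tumor, provider, panel, gel_screen, gel_high,
                      case_id="demo")
print(f"status={result.status}  escalated={result.escalated}")
for c in result.marker_calls:
    print(f"{c.marker:7s} tier={c.tier:9s} shift={c.shift_bp:+d} bp "
          f"new_bands={[round(b,1) for b in c.new_minor_bands]} "
          f"unstable={c.unstable}")
```

prints

```
status=MSI-H  escalated=True
NR-27   tier=screening shift=+0 bp new_bands=[] unstable=False
NR-21   tier=highres   shift=+0 bp new_bands=[107.6] unstable=True
BAT-25  tier=screening shift=+0 bp new_bands=[] unstable=False
NR-24   tier=screening shift=-1 bp new_bands=[] unstable=False
BAT-26  tier=highres   shift=+0 bp new_bands=[230.6] unstable=True
```

At 35% tumour fraction the deleted alleles merge into the germline band on
the screening gel, so both truly unstable markers are flagged as inconclusive
smears and escalated; on the high-resolution gel they resolve into new minor
bands 12 and 14 bp below the germline products (120 → 107.6, 245 → 230.6),
each marker becomes unstable, and two unstable markers classify the case
MSI-H. The three stable markers keep their screening-tier calls.

The same workflow is available from the shell:

```
msicall simulate --config config.yaml --out run/
msicall analyze --traces traces.tsv --samplesheet sheet.tsv --ihc ihc.tsv --out run/
msicall lod --flags dilution_calls.tsv --out lod.tsv
msicall concordance --cohort run/cohort_status.tsv --ihc ihc.tsv --out concordance.json
```

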