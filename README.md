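# oreo-pseu

Targeted quantification of mRNA pseudouridine (Ψ) from direct RNA sequencing
alignments, BID-seq deletion signatures, and reporter flow cytometry — with a
ground-truth simulator so the whole pipeline is testable without sequencing
data.

## Who this is for

Groups engineering guide-RNA-directed pseudouridine synthases (e.g.
DKC1/H-ACA systems recruited to a premature stop codon to drive readthrough)
who need to answer, per target uridine: *what fraction of transcripts is
modified, and how selective is the targeting between a recruited reporter
(mCherry) and an untagged bystander (eGFP)?*

## The statistics at the core

**Per-read Ψ call (direct RNA).** Ψ perturbs nanopore current so the
basecaller tends to miscall the modified U as C, and a Ψ-aware model emits a
per-base modification probability stored in SAM `MM`/`ML` tags as a code
`c ∈ {0..255}`, decoded as the bin midpoint `p = (2c + 1)/512`. A read *i*
covering target site *s* is called modified by the union rule

```
modified(i, s) = [base(i, s) = C]  ∨  [p(i, s) > τ],        τ = 0.95 (strict)
```

**Site stoichiometry and fold change.** With n reads covering *s* with a base
call (deletion-bearing and non-covering reads excluded),

```
pct_raw(s)       = 100 · #modified / n
pct_corrected(s) = max(0, pct_raw(s) − pct_raw_control(s))
fold change      = pct_corrected(mCherry site) / pct_corrected(eGFP site)
```

where the control is a non-targeting-guide sample measured at the same site.

**BID-seq.** Bisulfite chemistry converts Ψ into deletions;
`del_score(pos) = #deletions / depth ∈ [0, 1]` estimates stoichiometry and
cross-validates the direct-RNA readout.

**Flow cytometry.** Against a reporter-only control, live cells are split
into quadrants (Q2 double-positive, Q4 double-negative, thresholds at the
99.9th percentile of the control's live population per channel). Efficiency
is the iRFP-normalized Q2 percentage; selectivity is
`median(mCherry) / median(eGFP)` over Q1∪Q2∪Q3, normalized to a
cytoplasmic-enzyme reference condition.

See `docs/methods.md` for the full model, numerical conventions, and
limitations.

## Worked example

Simulate a targeted sample (30% of molecules modified at both reporter
targets) plus an unmodified control, then quantify:

```python
from oreo import DrsSimConfig, make_reference, run_pseucall, simulate_drs_reads
from oreo.pipeline import SYNTHETIC_EGFP_MOTIF, SYNTHETIC_MCHERRY_MOTIF

ref = make_reference(SYNTHETIC_EGFP_MOTIF, SYNTHETIC_MCHERRY_MOTIF, flank_len=50, seed=7)
sample = simulate_drs_reads(ref, DrsSimConfig(n_reads=20000, frac_modified=0.30, seed=1), "demo/sample")
control = simulate_drs_reads(ref, DrsSimConfig(n_reads=20000, frac_modified=0.0, seed=2), "demo/control")
report = run_pseucall(sample.bam_path, control.bam_path, ref,
                      sample_label="targeted", control_label="control")
cols = ["sample", "ref_name", "display_position", "n_reads", "pct_u_to_c",
        "pct_modified_raw", "pct_modified_corrected", "fold_change_target_over_offtarget"]
print(report[cols].round(2).to_string(index=False))
```

prints

```
  sample ref_name  display_position  n_reads  pct_u_to_c  pct_modified_raw  pct_modified_corrected  fold_change_target_over_offtarget
targeted     eGFP                56    20000       29.90             32.66                   28.04                               0.97
 control     eGFP                56    20000        4.11              4.63                    0.00                                NaN
targeted  mCherry                56    20000       11.10             28.53                   27.14                               0.97
```

Reading it: the U→C mismatch rate is strongly motif-dependent (29.9% at the
eGFP motif vs 11.1% at mCherry for the same 30% true stoichiometry — the
mCherry motif miscalls less often), but the union with the probability-tag
channel plus control subtraction recovers ~28%/27% at both sites, and the
mCherry/eGFP fold change is ~1 as expected when both sites are modified
equally. The control rows show the background call rate (4.6%/1.4%) that the
subtraction removes.

The same stages are available from a shell:

```bash
oreo simulate drs --out sim --seed 1
oreo pileup   --bam sim/drs.bam --ref sim/drs.fa --sites sim/sites.tsv --out qc
oreo pseucall --sample sample.bam --control control.bam --ref ref.fa --sites sites.tsv --out out
oreo bidseq   --bam bid.bam --ref ref.fa --sites sites.tsv --out out_bid
oreo flow selectivity --events oreo.csv --control reporter_only.csv --reference nes.csv --out sel
oreo scenario oreo_vs_nes --out scenario_out --seed 1
```

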