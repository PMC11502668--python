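"""Deletion-signature quantification (BID-seq readout).

Bisulfite treatment converts pseudouridine sites into deletions in the
sequenced library, so the per-position deletion fraction — the ``del_score``
in [0, 1] — estimates site stoichiometry (0 = unmodified, 1 = fully
modified). Depth at a position counts every aligned read whose alignment
spans it (deletion-bearing reads included, soft-clipped-away reads not);
multi-base deletions count once at each covered position. No depth or
quality filter is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import InputError, UndefinedResultError
from .simdata import ReferenceSet


@dataclass(frozen=True)
class BidSeqSite:
    """Deletion evidence at one reference position."""

    ref_name: str
    position: int
    depth: int
    n_deletions: int

    @property
    def del_score(self) -> float:
        if self.depth == 0:
            raise UndefinedResultError(
                f"del_score undefined at {self.ref_name}:{self.position}: depth 0"
            )
        return self.n_deletions / self.depth


def count_deletions(bam_path: str | Path, ref: ReferenceSet) -> pd.DataFrame:
    """Per-position depth, deletion count, and del_score for every reference position.

    Zero-coverage positions are reported with depth 0 and del_score missing
    (NaN), never 0.
    """
    bam_path = Path(bam_path)
    if not bam_path.exists():
        raise InputError(f"BAM not found: {bam_path}")
    with pysam.AlignmentFile(str(bam_path)) as bam:
        if not bam.has_index():
            raise InputError(f"BAM index (.bai) missing for {bam_path}")
        missing = [n for n in ref.names if n not in bam.references]
        if missing:
            raise InputError(f"references absent from BAM header: {missing}")
        rows = []
        for name, seq in ref.records:
            L = len(seq)
            # difference arrays over reference positions; one CIGAR walk per read
            depth_diff = np.zeros(L + 1, dtype=np.int64)
            del_diff = np.zeros(L + 1, dtype=np.int64)
            for read in bam.fetch(name):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                start, end = read.reference_start, read.reference_end
                depth_diff[start] += 1
                depth_diff[min(end, L)] -= 1
                rpos = start
                for op, length in read.cigartuples:
                    if op in (0, 7, 8):  # M/=/X
                        rpos += length
                    elif op == 2:  # D: spans the position, counted as deletion
                        del_diff[rpos] += 1
                        del_diff[min(rpos + length, L)] -= 1
                        rpos += length
                    elif op == 3:  # N: spans but contributes no molecule evidence
                        depth_diff[rpos] -= 1
                        depth_diff[min(rpos + length, L)] += 1
                        rpos += length
            depth = np.cumsum(depth_diff[:L])
            dels = np.cumsum(del_diff[:L])
            for pos in range(L):
                rows.append(
                    {
                        "ref_name": name,
                        "position": pos,
                        "display_position": pos + 1,
                        "ref_base": seq[pos],
                        "depth": int(depth[pos]),
                        "n_deletions": int(dels[pos]),
                        "del_score": dels[pos] / depth[pos] if depth[pos] > 0 else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def site_from_table(table: pd.DataFrame, ref_name: str, position: int) -> BidSeqSite:
    """Extract one position from a :func:`count_deletions` table."""
    hit = table[(table["ref_name"] == ref_name) & (table["position"] == position)]
    if hit.empty:
        raise InputError(f"{ref_name}:{position} not in deletion table")
    row = hit.iloc[0]
    return BidSeqSite(
        ref_name=ref_name,
        position=position,
        depth=int(row["depth"]),
        n_deletions=int(row["n_deletions"]),
    )


def bidseq_fold_change(target_site: BidSeqSite, offtarget_site: BidSeqSite) -> float:
    """Ratio of del_scores, target over off-target."""
    off = offtarget_site.del_score
    if off == 0:
        raise UndefinedResultError(
            f"off-target del_score is 0 at {offtarget_site.ref_name}:"
            f"{offtarget_site.position}; fold change undefined"
        )
    return target_site.del_score / off
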