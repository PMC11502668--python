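"""Per-position base composition, accuracy metrics, and context profiles.

The composition matrix is built with pysam's pileup engine (stepper
"samtools") with the quality filter applied here rather than inside the
engine, so that deletions are counted regardless of base quality while base
calls below ``min_base_quality`` are excluded. 'N' base calls are excluded
from both numerator and denominator; insertions consume no reference
position and are ignored. Depth is capped at ``max_depth`` per column, with
reads truncated deterministically in BAM order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import ConfigError, InputError, UndefinedResultError
from .simdata import ReferenceSet, TargetSite

BASE_COLUMNS = ("A", "C", "G", "T")

DEFAULT_MAX_DEPTH_ACCURACY = 10_000
DEFAULT_MIN_BASE_QUALITY = 13


@dataclass
class PileupMatrix:
    """Per-(reference, position) base/deletion composition.

    ``table`` has one row per reference position (zero-coverage positions
    included with depth 0) with columns: ref_name, position, ref_base,
    A/C/G/T/deletion counts, depth, match_pct, mismatch_pct_{A,C,G,T},
    del_pct, mismatch_pct (total non-reference, incl. deletions).
    """

    table: pd.DataFrame
    max_depth: int
    min_base_quality: int

    def row(self, ref_name: str, position: int) -> pd.Series:
        t = self.table
        hit = t[(t["ref_name"] == ref_name) & (t["position"] == position)]
        if hit.empty:
            raise KeyError(f"{ref_name}:{position} not in pileup")
        return hit.iloc[0]

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False)
        return path


def build_pileup(
    bam_path: str | Path,
    ref: ReferenceSet,
    max_depth: int = DEFAULT_MAX_DEPTH_ACCURACY,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> PileupMatrix:
    """Count A/C/G/T/deletion per reference position from a sorted+indexed BAM."""
    if max_depth <= 0:
        raise ConfigError(f"max_depth must be > 0, got {max_depth}")
    if min_base_quality < 0:
        raise ConfigError(f"min_base_quality must be >= 0, got {min_base_quality}")
    bam_path = Path(bam_path)
    if not bam_path.exists():
        raise InputError(f"BAM not found: {bam_path}")
    with pysam.AlignmentFile(str(bam_path)) as bam:
        if not bam.has_index():
            raise InputError(f"BAM index (.bai) missing for {bam_path}")
        missing = [n for n in ref.names if n not in bam.references]
        if missing:
            raise InputError(
                f"references absent from BAM header: {missing} (BAM has {list(bam.references)})"
            )
        rows = []
        for name, seq in ref.records:
            L = len(seq)
            counts = {b: np.zeros(L, dtype=np.int64) for b in BASE_COLUMNS}
            dels = np.zeros(L, dtype=np.int64)
            # engine-level quality filter disabled: deletions must be counted
            # regardless of quality; base quality is checked per base below
            for column in bam.pileup(
                name,
                0,
                L,
                truncate=True,
                max_depth=max_depth,
                min_base_quality=0,
                stepper="samtools",
            ):
                pos = column.reference_pos
                for pr in column.pileups:
                    if pr.is_refskip:
                        continue
                    if pr.is_del:
                        dels[pos] += 1
                        continue
                    qpos = pr.query_position
                    base = pr.alignment.query_sequence[qpos]
                    if base == "N":
                        continue
                    quals = pr.alignment.query_qualities
                    if quals is not None and quals[qpos] < min_base_quality:
                        continue
                    if base in counts:
                        counts[base][pos] += 1
            for pos in range(L):
                rows.append(
                    {
                        "ref_name": name,
                        "position": pos,
                        "ref_base": seq[pos],
                        **{b: int(counts[b][pos]) for b in BASE_COLUMNS},
                        "deletion": int(dels[pos]),
                    }
                )
    table = pd.DataFrame(rows)
    depth = table[list(BASE_COLUMNS)].sum(axis=1) + table["deletion"]
    table["depth"] = depth
    with np.errstate(invalid="ignore", divide="ignore"):
        ref_count = np.array(
            [
                table.loc[i, rb] if rb in BASE_COLUMNS else 0
                for i, rb in enumerate(table["ref_base"])
            ],
            dtype=float,
        )
        table["match_pct"] = np.where(depth > 0, 100.0 * ref_count / depth, np.nan)
        for b in BASE_COLUMNS:
            is_ref = (table["ref_base"] == b).to_numpy()
            pct = np.where(depth > 0, 100.0 * table[b] / depth, np.nan)
            table[f"mismatch_pct_{b}"] = np.where(is_ref, 0.0, pct)
        table["del_pct"] = np.where(depth > 0, 100.0 * table["deletion"] / depth, np.nan)
    table["mismatch_pct"] = np.where(
        depth > 0, 100.0 - table["match_pct"], np.nan
    )
    return PileupMatrix(table=table, max_depth=max_depth, min_base_quality=min_base_quality)


def mean_base_accuracy(p: PileupMatrix) -> float:
    """Depth-weighted mean per-position match percentage over covered positions."""
    covered = p.table[p.table["depth"] > 0]
    if covered.empty:
        raise UndefinedResultError("no covered positions; mean base accuracy undefined")
    total_depth = covered["depth"].sum()
    weighted = (covered["match_pct"] * covered["depth"]).sum()
    return float(weighted / total_depth)


def context_profile(p: PileupMatrix, site, window: int = 5) -> pd.DataFrame:
    """Composition at offsets −window..+window around a target site.

    The offset-0 row is the target-site composition itself.
    """
    if window < 0:
        raise ConfigError(f"window must be >= 0, got {window}")
    if hasattr(site, "ref_name"):
        ref_name, position = site.ref_name, int(site.position)
    else:
        ref_name, position = str(site[0]), int(site[1])
    sub = p.table[p.table["ref_name"] == ref_name]
    if sub.empty:
        raise InputError(f"reference {ref_name!r} not in pileup")
    max_pos = int(sub["position"].max())
    if position - window < 0 or position + window > max_pos:
        raise ConfigError(
            f"window {window} around {ref_name}:{position} exceeds reference "
            f"bounds [0, {max_pos}]"
        )
    out = sub[(sub["position"] >= position - window) & (sub["position"] <= position + window)].copy()
    out.insert(0, "offset", out["position"] - position)
    return out.sort_values("offset").reset_index(drop=True)
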