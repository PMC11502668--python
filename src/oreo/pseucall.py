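"""Per-read pseudouridine classification and site stoichiometry.

A read is called modified at a target uridine when it shows the
characteristic U→C basecalling mismatch **or** carries a high-confidence
modification-probability tag (decoded p strictly above the threshold,
default 0.95) — the union of the two evidence channels. Site stoichiometry
is the percentage of modified reads among reads that cover the site with a
base call (deletion-bearing and non-covering reads are excluded from the
denominator); a matched control sample's percentage is subtracted per site
to remove motif-specific background error, clamping at zero.

Probability tags follow the SAM base-modification convention: an integer
code 0–255 per tagged base, decoded to the midpoint of its probability bin,
decode(c) = (2c + 1) / 512. Encoding is encode(p) = min(255, floor(256 p)),
so the round trip is exact on all 256 codes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import ConfigError, InputError, UndefinedResultError

if TYPE_CHECKING:  # pragma: no cover
    from .simdata import ReferenceSet, TargetSite

#: ChEBI code for pseudouridine in SAM MM tags.
PSEU_MOD_CODE = 17802

DEFAULT_THRESHOLD = 0.95
DEFAULT_MAX_DEPTH_MODCALL = 100_000


# ---------------------------------------------------------------------------
# probability codes
# ---------------------------------------------------------------------------


def decode_probability(code: int) -> float:
    """Decode an integer tag code 0–255 to its bin-midpoint probability."""
    code = int(code)
    if not 0 <= code <= 255:
        raise ConfigError(f"probability code must be in [0, 255], got {code}")
    return (2 * code + 1) / 512.0


def encode_probability(p: float) -> int:
    """Encode a probability in [0, 1] to its integer tag code 0–255."""
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"probability must be in [0, 1], got {p}")
    return min(255, int(p * 256))


def smallest_code_above(threshold: float = DEFAULT_THRESHOLD) -> int:
    """Smallest code whose decoded probability strictly exceeds ``threshold``."""
    for code in range(256):
        if decode_probability(code) > threshold:
            return code
    raise ConfigError(f"no code decodes above {threshold}")


# ---------------------------------------------------------------------------
# per-read classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadClassification:
    """Evidence at one target site for one read.

    ``observed_base`` is one of A/C/G/T, "deletion", or "none" (read does not
    cover the site). ``decoded_p`` is None when the read carries no
    probability tag at the site.
    """

    read_id: str
    ref_name: str
    position: int
    observed_base: str
    u_to_c: bool
    decoded_p: float | None
    high_conf_call: bool
    modified: bool

    @property
    def covers_site(self) -> bool:
        return self.observed_base not in ("none", "deletion")


def _site_tuple(site) -> tuple[str, int]:
    if hasattr(site, "ref_name"):
        return site.ref_name, int(site.position)
    ref_name, position = site
    return str(ref_name), int(position)


def _decoded_p_at(read: pysam.AlignedSegment, query_pos: int) -> float | None:
    """Decoded pseudouridine probability tagged at a query position, if any."""
    mods = read.modified_bases
    if not mods:
        return None
    for (_canonical, strand, code), entries in mods.items():
        if code != PSEU_MOD_CODE or strand != 0:
            continue
        for qpos, tag_code in entries:
            if qpos == query_pos and tag_code >= 0:
                return decode_probability(tag_code)
    return None


def classify_read(
    read: pysam.AlignedSegment,
    site,
    threshold: float = DEFAULT_THRESHOLD,
    ref_base: str = "T",
) -> ReadClassification:
    """Classify one aligned read at a target uridine site.

    ``u_to_c`` is true iff the base call at the site is C; ``high_conf_call``
    iff a probability tag at the site decodes strictly above ``threshold``;
    ``modified`` is their union. Reads that do not cover the site, or show a
    deletion at it, come back with ``modified=False`` and a distinct
    ``observed_base`` so callers can exclude them from denominators.
    """
    if ref_base != "T":
        raise ConfigError(f"target site reference base must be 'T', got {ref_base!r}")
    ref_name, position = _site_tuple(site)
    observed = "none"
    decoded_p: float | None = None
    if read.reference_start <= position < (read.reference_end or read.reference_start):
        observed = "deletion"
        for qpos, rpos in read.get_aligned_pairs():
            if rpos == position:
                if qpos is not None:
                    observed = read.query_sequence[qpos]
                    decoded_p = _decoded_p_at(read, qpos)
                break
    u_to_c = observed == "C"
    high_conf = decoded_p is not None and decoded_p > threshold
    covering = observed not in ("none", "deletion")
    return ReadClassification(
        read_id=read.query_name,
        ref_name=ref_name,
        position=position,
        observed_base=observed,
        u_to_c=u_to_c,
        decoded_p=decoded_p,
        high_conf_call=high_conf,
        modified=covering and (u_to_c or high_conf),
    )


# ---------------------------------------------------------------------------
# site summaries
# ---------------------------------------------------------------------------


@dataclass
class SiteModificationSummary:
    """Read-count and percent-modified summary at one site for one sample."""

    sample_label: str
    ref_name: str
    position: int
    n_reads_covering: int
    n_u_to_c: int
    n_high_conf_only: int
    n_modified: int
    pct_u_to_c: float
    pct_high_conf_only: float
    pct_modified_raw: float
    pct_modified_corrected: float | None = None
    control_pct: float | None = None
    clamped: bool = False

    @property
    def display_position(self) -> int:
        return self.position + 1


def summarize_site(
    classifications: Iterable[ReadClassification],
    sample_label: str = "sample",
    exclude_noncovering: bool = True,
) -> SiteModificationSummary:
    """Aggregate per-read calls into site stoichiometry.

    The denominator is the number of reads covering the site with a base call
    (deletions and non-covering reads excluded when ``exclude_noncovering``);
    zero usable reads is an undefined result, never reported as 0%.
    """
    cls = list(classifications)
    if not cls:
        raise UndefinedResultError("no read classifications supplied")
    ref_names = {c.ref_name for c in cls}
    positions = {c.position for c in cls}
    if len(ref_names) > 1 or len(positions) > 1:
        raise ConfigError(f"classifications mix sites: {sorted(ref_names)} x {sorted(positions)}")
    if exclude_noncovering:
        usable = [c for c in cls if c.covers_site]
    else:
        usable = cls
    n = len(usable)
    if n == 0:
        raise UndefinedResultError(
            f"no usable reads at {next(iter(ref_names))}:{next(iter(positions))} "
            "(all non-covering or deletion-bearing)"
        )
    n_u2c = sum(c.u_to_c for c in usable)
    n_mod = sum(c.modified for c in usable)
    n_hc_only = sum(c.high_conf_call and not c.u_to_c for c in usable)
    return SiteModificationSummary(
        sample_label=sample_label,
        ref_name=next(iter(ref_names)),
        position=next(iter(positions)),
        n_reads_covering=n,
        n_u_to_c=n_u2c,
        n_high_conf_only=n_hc_only,
        n_modified=n_mod,
        pct_u_to_c=100.0 * n_u2c / n,
        pct_high_conf_only=100.0 * n_hc_only / n,
        pct_modified_raw=100.0 * n_mod / n,
    )


def subtract_control(
    sample: SiteModificationSummary, control: SiteModificationSummary
) -> SiteModificationSummary:
    """Subtract the control sample's raw percent-modified at the same site.

    Negative differences clamp to 0 (a proportion cannot be negative); the
    clamping is recorded on the returned summary.
    """
    if (sample.ref_name, sample.position) != (control.ref_name, control.position):
        raise ConfigError(
            f"site mismatch: sample {sample.ref_name}:{sample.position} vs "
            f"control {control.ref_name}:{control.position}"
        )
    diff = sample.pct_modified_raw - control.pct_modified_raw
    return replace(
        sample,
        pct_modified_corrected=max(0.0, diff),
        control_pct=control.pct_modified_raw,
        clamped=diff < 0,
    )


@dataclass(frozen=True)
class FoldChangeResult:
    """Ratio of corrected percent-modified between the on- and off-target site."""

    target_ref: str
    offtarget_ref: str
    target_pct: float
    offtarget_pct: float
    fold_change: float


def fold_change(
    target: SiteModificationSummary, offtarget: SiteModificationSummary
) -> FoldChangeResult:
    """Corrected-percentage fold change, target site over off-target site."""
    if target.pct_modified_corrected is None or offtarget.pct_modified_corrected is None:
        raise ConfigError("fold_change requires control-corrected summaries")
    if offtarget.pct_modified_corrected == 0:
        resolution = 100.0 / offtarget.n_reads_covering
        raise UndefinedResultError(
            "off-target corrected percent is 0; fold change undefined "
            f"(>= {target.pct_modified_corrected / resolution:.1f} at this depth)"
        )
    return FoldChangeResult(
        target_ref=target.ref_name,
        offtarget_ref=offtarget.ref_name,
        target_pct=target.pct_modified_corrected,
        offtarget_pct=offtarget.pct_modified_corrected,
        fold_change=target.pct_modified_corrected / offtarget.pct_modified_corrected,
    )


# ---------------------------------------------------------------------------
# orchestration over BAM files
# ---------------------------------------------------------------------------


def _require_index(bam_path: str | Path) -> pysam.AlignmentFile:
    bam_path = Path(bam_path)
    if not bam_path.exists():
        raise InputError(f"BAM not found: {bam_path}")
    try:
        bam = pysam.AlignmentFile(str(bam_path))
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot open BAM {bam_path}: {exc}") from exc
    if not bam.has_index():
        bam.close()
        raise InputError(f"BAM index (.bai) missing for {bam_path}; sort and index first")
    return bam


def classify_site_in_bam(
    bam_path: str | Path,
    site,
    threshold: float = DEFAULT_THRESHOLD,
    max_depth: int = DEFAULT_MAX_DEPTH_MODCALL,
) -> list[ReadClassification]:
    """Classify every read overlapping a site, truncating at ``max_depth``
    in BAM (coordinate) order for reproducibility."""
    ref_name, position = _site_tuple(site)
    out: list[ReadClassification] = []
    with _require_index(bam_path) as bam:
        if ref_name not in bam.references:
            raise InputError(f"reference {ref_name!r} not in BAM header ({list(bam.references)})")
        for read in bam.fetch(ref_name, position, position + 1):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            out.append(classify_read(read, (ref_name, position), threshold=threshold))
            if len(out) >= max_depth:
                break
    return out


def run_pseucall(
    sample_bam: str | Path,
    control_bam: str | Path,
    ref: "ReferenceSet",
    sites: Sequence | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    max_depth: int = DEFAULT_MAX_DEPTH_MODCALL,
    sample_label: str = "sample",
    control_label: str = "control",
    fold_change_pair: tuple[str, str] | None = ("mCherry", "eGFP"),
) -> pd.DataFrame:
    """Classify sample and control at each target site and tabulate results.

    One row per (sample, site) with read counts, component percentages
    (mismatch-only, high-confidence-tag-only), raw and control-corrected
    percent-modified. When ``fold_change_pair`` names two references present
    among the sites, the corrected-percentage fold change target/off-target is
    attached to the sample rows (NaN plus a lower bound when the off-target
    corrected percent is zero).
    """
    if not 0.0 < threshold < 1.0:
        raise ConfigError(f"threshold must be in (0, 1), got {threshold}")
    if sites is None:
        sites = list(ref.target_sites)
    site_tuples = [_site_tuple(s) for s in sites]
    for ref_name, position in site_tuples:
        if ref.sequence(ref_name)[position] != "T":
            raise ConfigError(f"site {ref_name}:{position} reference base is not 'T'")
    # fail fast on missing indexes before any computation
    _require_index(sample_bam).close()
    _require_index(control_bam).close()

    summaries: dict[tuple[str, str, int], SiteModificationSummary] = {}
    for label, bam_path in ((sample_label, sample_bam), (control_label, control_bam)):
        for ref_name, position in site_tuples:
            cls = classify_site_in_bam(bam_path, (ref_name, position), threshold, max_depth)
            summaries[(label, ref_name, position)] = summarize_site(cls, sample_label=label)
    corrected: dict[tuple[str, str, int], SiteModificationSummary] = {}
    for ref_name, position in site_tuples:
        control = summaries[(control_label, ref_name, position)]
        corrected[(sample_label, ref_name, position)] = subtract_control(
            summaries[(sample_label, ref_name, position)], control
        )
        corrected[(control_label, ref_name, position)] = subtract_control(control, control)

    rows = []
    for (label, ref_name, position), s in corrected.items():
        rows.append(
            {
                "sample": label,
                "ref_name": ref_name,
                "position": position,
                "display_position": position + 1,
                "n_reads": s.n_reads_covering,
                "n_u_to_c": s.n_u_to_c,
                "n_high_conf_only": s.n_high_conf_only,
                "n_modified": s.n_modified,
                "pct_u_to_c": s.pct_u_to_c,
                "pct_high_conf_only": s.pct_high_conf_only,
                "pct_modified_raw": s.pct_modified_raw,
                "control_pct": s.control_pct,
                "pct_modified_corrected": s.pct_modified_corrected,
                "clamped": s.clamped,
            }
        )
    report = pd.DataFrame(rows)

    if fold_change_pair is not None:
        target_ref, offtarget_ref = fold_change_pair
        by_ref = {ref_name for ref_name, _ in site_tuples}
        if target_ref in by_ref and offtarget_ref in by_ref:
            fc_vals, fc_bounds = [], []
            for label in report["sample"]:
                tgt = next(
                    corrected[k] for k in corrected if k[0] == label and k[1] == target_ref
                )
                off = next(
                    corrected[k] for k in corrected if k[0] == label and k[1] == offtarget_ref
                )
                try:
                    fc_vals.append(fold_change(tgt, off).fold_change)
                    fc_bounds.append(np.nan)
                except UndefinedResultError:
                    fc_vals.append(np.nan)
                    resolution = 100.0 / off.n_reads_covering
                    fc_bounds.append(
                        tgt.pct_modified_corrected / resolution
                        if tgt.pct_modified_corrected
                        else 0.0
                    )
            report["fold_change_target_over_offtarget"] = fc_vals
            report["fold_change_lower_bound"] = fc_bounds
    return report
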