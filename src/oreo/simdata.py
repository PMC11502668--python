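"""Synthetic inputs with known ground truth for every downstream stage.

Three generators:

* :func:`simulate_drs_reads` — direct-RNA-sequencing-like alignments over short
  reporter references. Each read is truly modified at the target uridine with
  probability ``frac_modified``; modified reads emit the characteristic U→C
  basecalling mismatch with a motif-dependent probability, and every read whose
  basecall at the target is still T carries a pseudouridine probability tag
  (SAM MM/ML, code 17802, '?' skip semantics) drawn from a status-conditional
  Beta distribution.
* :func:`simulate_bidseq_reads` — bisulfite-induced-deletion-like alignments:
  modified molecules carry a deletion at the target position.
* :func:`simulate_flow_events` — per-cell fluorescence intensity tables with
  log-normal subpopulations (untransfected / transfected low / transfected
  high / dead).

Coordinates are 0-based half-open throughout; RNA is written in the DNA
alphabet (T for U) to match alignment-format conventions. All reads map to
the forward strand. Outputs are byte-identical for a fixed seed: records are
generated in coordinate-sorted order and written directly, so no re-sorting
step (with its run-specific @PG header line) is needed.
"""

from __future__ import annotations

import math
from array import array
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import ConfigError, InputError
from .pseucall import PSEU_MOD_CODE, encode_probability, smallest_code_above

ALPHABET = set("ACGTN")
_BASES = np.array(list("ACGT"))

# U→C mismatch emission rates measured on fully modified / unmodified synthetic
# oligos for the two reporter motifs; used as the default simulation settings.
DEFAULT_P_MISMATCH_GIVEN_MOD = {"eGFP": 0.883, "mCherry": 0.342}
DEFAULT_P_MISMATCH_GIVEN_UNMOD = {"eGFP": 0.039, "mCherry": 0.013}

# Upper-tail mass (above the high-confidence probability cut) of the
# modification-probability tag, calibrated so that the union of mismatch and
# high-confidence tag calls reproduces the oligo benchmark percentages
# (96.6/91.8% for fully modified, 4.4/1.4% for unmodified eGFP/mCherry).
DEFAULT_TAG_TAIL_MOD = {
    "eGFP": (0.966 - 0.883) / (1.0 - 0.883),
    "mCherry": (0.918 - 0.342) / (1.0 - 0.342),
}
DEFAULT_TAG_TAIL_UNMOD = {
    "eGFP": (0.044 - 0.039) / (1.0 - 0.039),
    "mCherry": (0.014 - 0.013) / (1.0 - 0.013),
}

FLOW_POPULATIONS = ("untransfected", "transfected_low", "transfected_high", "dead")
FLOW_CHANNELS = ("gfp", "mcherry", "irfp", "viability")

DEFAULT_FLOW_FRACTIONS = {
    "untransfected": 0.40,
    "transfected_low": 0.20,
    "transfected_high": 0.30,
    "dead": 0.10,
}

# (mu, sigma) of natural-log intensity per subpopulation and channel,
# in arbitrary cytometer units. Transfected cells express the reporters and
# the iRFP transfection marker; dead cells take up the viability dye.
_BG = (math.log(80.0), 0.5)
_LIVE_DYE = (math.log(50.0), 0.4)
DEFAULT_FLOW_CHANNELS: dict[str, dict[str, tuple[float, float]]] = {
    "untransfected": {"gfp": _BG, "mcherry": _BG, "irfp": (math.log(100.0), 0.5), "viability": _LIVE_DYE},
    "transfected_low": {
        "gfp": (math.log(1200.0), 0.6),
        "mcherry": (math.log(1200.0), 0.6),
        "irfp": (math.log(20000.0), 0.7),
        "viability": _LIVE_DYE,
    },
    "transfected_high": {
        "gfp": (math.log(4000.0), 0.6),
        "mcherry": (math.log(4000.0), 0.6),
        "irfp": (math.log(60000.0), 0.7),
        "viability": _LIVE_DYE,
    },
    "dead": {
        "gfp": (math.log(150.0), 0.8),
        "mcherry": (math.log(150.0), 0.8),
        "irfp": (math.log(150.0), 0.8),
        "viability": (math.log(5000.0), 0.5),
    },
}


# ---------------------------------------------------------------------------
# references
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetSite:
    """A single annotated target uridine (0-based position, reference base T)."""

    ref_name: str
    position: int

    @property
    def display_position(self) -> int:
        """1-based position for human-readable reports."""
        return self.position + 1


@dataclass
class ReferenceSet:
    """Reporter reference sequences plus their annotated target uridines."""

    records: list[tuple[str, str]]
    target_sites: list[TargetSite]
    context_window: int = 5

    def __post_init__(self) -> None:
        names = [n for n, _ in self.records]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate reference names: {names}")
        for name, seq in self.records:
            if not seq:
                raise ConfigError(f"reference {name!r} is empty")
            bad = set(seq) - ALPHABET
            if bad:
                raise ConfigError(f"reference {name!r} has invalid characters {sorted(bad)}")
        by_name = dict(self.records)
        for site in self.target_sites:
            if site.ref_name not in by_name:
                raise ConfigError(f"target site on unknown reference {site.ref_name!r}")
            seq = by_name[site.ref_name]
            if not 0 <= site.position < len(seq):
                raise ConfigError(f"target position {site.position} outside {site.ref_name!r}")
            if seq[site.position] != "T":
                raise ConfigError(
                    f"target position {site.position} of {site.ref_name!r} is "
                    f"{seq[site.position]!r}, expected 'T'"
                )

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.records]

    def sequence(self, name: str) -> str:
        for n, s in self.records:
            if n == name:
                return s
        raise KeyError(name)

    def sites_for(self, name: str) -> list[TargetSite]:
        return [s for s in self.target_sites if s.ref_name == name]

    def write_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for name, seq in self.records:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        pysam.faidx(str(path))
        return path

    def write_sites_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(
            {
                "ref_name": [s.ref_name for s in self.target_sites],
                "position": [s.position for s in self.target_sites],
                "display_position": [s.display_position for s in self.target_sites],
            }
        )
        df.to_csv(path, sep="\t", index=False)
        return path

    def bam_header(self) -> dict:
        return {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": len(s)} for n, s in self.records],
        }


def reference_from_fasta(fasta: str | Path, sites: Sequence[tuple[str, int]] | str | Path) -> ReferenceSet:
    """Load a ReferenceSet from a FASTA file plus target sites.

    ``sites`` is either a list of (ref_name, 0-based position) pairs or a path
    to a TSV with columns ``ref_name`` and ``position``.
    """
    fasta = Path(fasta)
    if not fasta.exists():
        raise InputError(f"FASTA not found: {fasta}")
    with pysam.FastaFile(str(fasta)) as fa:
        records = [(name, fa.fetch(name).upper()) for name in fa.references]
    if isinstance(sites, (str, Path)):
        df = pd.read_csv(sites, sep="\t")
        sites = list(zip(df["ref_name"], df["position"].astype(int)))
    target_sites = [TargetSite(str(r), int(p)) for r, p in sites]
    return ReferenceSet(records=records, target_sites=target_sites)


def make_reference(
    egfp_motif: str,
    mcherry_motif: str,
    flank_len: int = 50,
    seed: int = 0,
    context_window: int = 5,
) -> ReferenceSet:
    """Build the two reporter references, each with one target uridine.

    Each motif (odd length, centered on the target T) is embedded between
    random flanks of ``flank_len`` bases; the target site is annotated at the
    motif center. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    records = []
    sites = []
    for name, motif in (("eGFP", egfp_motif), ("mCherry", mcherry_motif)):
        motif = motif.upper()
        if len(motif) % 2 != 1:
            raise ConfigError(f"{name} motif must have odd length, got {len(motif)}")
        bad = set(motif) - set("ACGT")
        if bad:
            raise ConfigError(f"{name} motif has invalid characters {sorted(bad)}")
        center = len(motif) // 2
        if motif[center] != "T":
            raise ConfigError(f"{name} motif center base is {motif[center]!r}, expected 'T'")
        if flank_len < context_window:
            raise ConfigError(f"flank_len {flank_len} < context window {context_window}")
        left = "".join(rng.choice(_BASES, size=flank_len))
        right = "".join(rng.choice(_BASES, size=flank_len))
        records.append((name, left + motif + right))
        sites.append(TargetSite(name, flank_len + center))
    return ReferenceSet(records=records, target_sites=sites, context_window=context_window)


# ---------------------------------------------------------------------------
# DRS read simulation
# ---------------------------------------------------------------------------


def high_conf_probability_cut(threshold: float = 0.95) -> float:
    """Smallest continuous probability whose encoded tag decodes above ``threshold``."""
    return smallest_code_above(threshold) / 256.0


def beta_params_for_tail(tail: float, kind: str, threshold: float = 0.95) -> tuple[float, float]:
    """One-parameter Beta family with prescribed mass above the encoding cut.

    For modified reads a Beta(a, 1) (mass piled near 1) with
    ``P(X > p*) = 1 - p***a = tail``; for unmodified a Beta(1, b) with
    ``P(X > p*) = (1 - p*)**b = tail``, where p* is the smallest probability
    whose encoded tag still clears ``threshold`` after decoding.
    """
    if not 0.0 < tail < 1.0:
        raise ConfigError(f"tail mass must be in (0, 1), got {tail}")
    p_star = high_conf_probability_cut(threshold)
    if kind == "modified":
        return (math.log(1.0 - tail) / math.log(p_star), 1.0)
    if kind == "unmodified":
        return (1.0, math.log(tail) / math.log(1.0 - p_star))
    raise ConfigError(f"unknown kind {kind!r}")


def _rate(value, ref_name: str, what: str) -> float:
    """Resolve a scalar-or-per-reference parameter for one reference."""
    if isinstance(value, Mapping):
        try:
            value = value[ref_name]
        except KeyError:
            raise ConfigError(
                f"{what} has no entry for reference {ref_name!r}; pass a scalar "
                "or add the reference to the mapping"
            ) from None
    return float(value)


def _check_rate(x: float, what: str) -> float:
    if not 0.0 <= x <= 1.0:
        raise ConfigError(f"{what} must be in [0, 1], got {x}")
    return x


@dataclass
class DrsSimConfig:
    """Conditions for one simulated direct-RNA run.

    Per-reference values (emission rates, Beta parameters) may be given as a
    scalar or as a mapping keyed by reference name. ``prob_dist_mod`` /
    ``prob_dist_unmod`` are Beta (alpha, beta) pairs; when left as None they
    are calibrated per reporter from the oligo-benchmark tail masses.
    """

    n_reads: int = 5000
    frac_modified: float = 1.0
    p_mismatch_given_mod: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_P_MISMATCH_GIVEN_MOD)
    )
    p_mismatch_given_unmod: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_P_MISMATCH_GIVEN_UNMOD)
    )
    background_sub_rate: float = 0.007
    background_del_rate: float = 0.003
    prob_dist_mod: tuple[float, float] | Mapping[str, tuple[float, float]] | None = None
    prob_dist_unmod: tuple[float, float] | Mapping[str, tuple[float, float]] | None = None
    read_span: tuple[int, int] | None = None
    base_quality: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ConfigError(f"n_reads must be >= 0, got {self.n_reads}")
        _check_rate(self.frac_modified, "frac_modified")
        _check_rate(self.background_sub_rate, "background_sub_rate")
        _check_rate(self.background_del_rate, "background_del_rate")

    def beta_params(self, ref_name: str, modified: bool) -> tuple[float, float]:
        value = self.prob_dist_mod if modified else self.prob_dist_unmod
        if value is None:
            tails = DEFAULT_TAG_TAIL_MOD if modified else DEFAULT_TAG_TAIL_UNMOD
            if ref_name not in tails:
                raise ConfigError(
                    f"no default probability-tag distribution for reference {ref_name!r}; "
                    "set prob_dist_mod/prob_dist_unmod explicitly"
                )
            return beta_params_for_tail(tails[ref_name], "modified" if modified else "unmodified")
        if isinstance(value, Mapping):
            try:
                value = value[ref_name]
            except KeyError:
                raise ConfigError(f"prob_dist has no entry for {ref_name!r}") from None
        a, b = float(value[0]), float(value[1])
        if a <= 0 or b <= 0:
            raise ConfigError(f"Beta parameters must be > 0, got ({a}, {b})")
        return a, b


@dataclass
class SimResult:
    """Paths of one simulated aligned read set plus its ground truth."""

    bam_path: Path
    fasta_path: Path
    truth_path: Path
    truth: pd.DataFrame


def _cigar_from_deletions(del_mask: np.ndarray) -> tuple[int, list[tuple[int, int]], np.ndarray]:
    """CIGAR for a full-span read given its per-reference-position deletion mask.

    Leading/trailing deletions are stripped (an alignment cannot start or end
    with D); returns (start offset within the span, cigartuples, kept mask).
    """
    kept = ~del_mask
    if not kept.any():
        return 0, [], kept
    first = int(np.argmax(kept))
    last = len(kept) - int(np.argmax(kept[::-1]))
    ops: list[tuple[int, int]] = []
    run_op = None
    run_len = 0
    for is_del in del_mask[first:last]:
        op = 2 if is_del else 0  # D / M
        if op == run_op:
            run_len += 1
        else:
            if run_op is not None:
                ops.append((run_op, run_len))
            run_op, run_len = op, 1
    ops.append((run_op, run_len))
    keep_full = np.zeros_like(kept)
    keep_full[first:last] = kept[first:last]
    return first, ops, keep_full


def _mm_ml_tags(query_seq: str, tagged: list[tuple[int, int]]) -> tuple[str, list[int]]:
    """SAM MM/ML strings for pseudouridine tags at the given query positions.

    ``tagged`` is a list of (query position, code); positions must hold 'T'.
    Uses '?' (unknown-if-untagged) skip semantics.
    """
    tagged = sorted(tagged)
    t_positions = [i for i, b in enumerate(query_seq) if b == "T"]
    t_rank = {pos: r for r, pos in enumerate(t_positions)}
    deltas = []
    prev_rank = -1
    for qpos, _ in tagged:
        rank = t_rank[qpos]
        deltas.append(rank - prev_rank - 1)
        prev_rank = rank
    mm = f"T+{PSEU_MOD_CODE}?," + ",".join(str(d) for d in deltas) + ";"
    return mm, [code for _, code in tagged]


def _open_out_bam(path: Path, ref: ReferenceSet) -> pysam.AlignmentFile:
    try:
        return pysam.AlignmentFile(str(path), "wb", header=ref.bam_header())
    except OSError as exc:  # pragma: no cover - exercised via error test
        raise InputError(f"cannot write BAM to {path}: {exc}") from exc


def simulate_drs_reads(
    ref: ReferenceSet,
    cfg: DrsSimConfig,
    out_dir: str | Path,
    prefix: str = "drs",
) -> SimResult:
    """Emit a sorted+indexed BAM of simulated direct-RNA reads plus ground truth.

    Per reference, ``cfg.n_reads`` forward-strand reads spanning
    ``cfg.read_span`` (default: the full reference). Each read's true
    modification status is Bernoulli(``frac_modified``) and applies at every
    annotated target site of its reference; at the target the read emits 'C'
    with the status-conditional mismatch probability, elsewhere background
    substitutions/deletions apply. Reads whose basecall at a target is 'T'
    carry an MM/ML pseudouridine probability tag drawn from the
    status-conditional Beta distribution.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out_dir}: {exc}") from exc
    fasta_path = ref.write_fasta(out_dir / f"{prefix}.fa")
    bam_path = out_dir / f"{prefix}.bam"
    rng = np.random.default_rng(cfg.seed)
    truth_rows: list[tuple[str, str, bool]] = []

    with _open_out_bam(bam_path, ref) as out:
        for tid, (name, seq) in enumerate(ref.records):
            L = len(seq)
            span = cfg.read_span or (0, L)
            start, end = span
            if not 0 <= start < end <= L:
                raise ConfigError(f"read_span {span} invalid for reference {name!r} of length {L}")
            n = cfg.n_reads
            if n == 0:
                continue
            p_mod = _check_rate(_rate(cfg.p_mismatch_given_mod, name, "p_mismatch_given_mod"), "p_mismatch_given_mod")
            p_unmod = _check_rate(
                _rate(cfg.p_mismatch_given_unmod, name, "p_mismatch_given_unmod"), "p_mismatch_given_unmod"
            )
            a_m, b_m = cfg.beta_params(name, modified=True)
            a_u, b_u = cfg.beta_params(name, modified=False)
            sites = [s.position for s in ref.sites_for(name)]
            in_span = [p for p in sites if start <= p < end]

            ref_arr = np.frombuffer(seq[start:end].encode(), dtype="S1").astype("U1")
            span_len = end - start
            true_mod = rng.random(n) < cfg.frac_modified
            del_mask = rng.random((n, span_len)) < cfg.background_del_rate
            sub_mask = (rng.random((n, span_len)) < cfg.background_sub_rate) & ~del_mask
            base_idx = {b: i for i, b in enumerate("ACGT")}
            base_mat = np.tile(ref_arr, (n, 1))
            # background substitutions rotate to one of the three other bases
            rot = rng.integers(1, 4, size=(n, span_len))
            ref_idx = np.array([base_idx.get(b, 0) for b in ref_arr])
            sub_base = _BASES[(ref_idx[None, :] + rot) % 4]
            base_mat[sub_mask] = sub_base[sub_mask]
            for pos in in_span:
                col = pos - start
                del_mask[:, col] = False
                sub_mask[:, col] = False
                p_mm = np.where(true_mod, p_mod, p_unmod)
                is_c = rng.random(n) < p_mm
                base_mat[:, col] = np.where(is_c, "C", "T")
            p_m_draw = rng.beta(a_m, b_m, size=(n, len(in_span))) if in_span else np.zeros((n, 0))
            p_u_draw = rng.beta(a_u, b_u, size=(n, len(in_span))) if in_span else np.zeros((n, 0))
            p_tag = np.where(true_mod[:, None], p_m_draw, p_u_draw)
            codes = np.minimum(255, (p_tag * 256).astype(np.int64))

            pending: list[pysam.AlignedSegment] = []
            for i in range(n):
                read_id = f"{name}_read{i:06d}"
                truth_rows.append((read_id, name, bool(true_mod[i])))
                offset, cigar, kept = _cigar_from_deletions(del_mask[i])
                if not cigar:
                    continue  # fully deleted read cannot be represented; n/a at default rates
                qseq = "".join(base_mat[i][kept])
                a = pysam.AlignedSegment(out.header)
                a.query_name = read_id
                a.query_sequence = qseq
                a.flag = 0
                a.reference_id = tid
                a.reference_start = start + offset
                a.mapping_quality = 60
                a.cigartuples = cigar
                a.query_qualities = pysam.qualitystring_to_array(chr(cfg.base_quality + 33) * len(qseq))
                tagged = []
                kept_cum = np.cumsum(kept) - 1  # query index per kept reference column
                for j, pos in enumerate(in_span):
                    col = pos - start
                    if base_mat[i, col] == "T" and kept[col]:
                        tagged.append((int(kept_cum[col]), int(codes[i, j])))
                if tagged:
                    mm, ml = _mm_ml_tags(qseq, tagged)
                    a.set_tag("MM", mm, "Z")
                    a.set_tag("ML", array("B", ml))
                pending.append(a)
            # leading background deletions shift starts; keep coordinate order
            pending.sort(key=lambda r: (r.reference_start, r.query_name))
            for a in pending:
                out.write(a)

    pysam.index(str(bam_path))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "ref_name", "true_modified"])
    truth_path = out_dir / f"{prefix}.truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimResult(bam_path=bam_path, fasta_path=fasta_path, truth_path=truth_path, truth=truth)


# ---------------------------------------------------------------------------
# BID-seq read simulation
# ---------------------------------------------------------------------------


def simulate_bidseq_reads(
    ref: ReferenceSet,
    n_reads: int,
    frac_modified: float | Mapping[str, float],
    p_del_given_mod: float | Mapping[str, float],
    p_del_given_unmod: float | Mapping[str, float],
    seed: int = 0,
    out_dir: str | Path = ".",
    prefix: str = "bidseq",
    background_del_rate: float = 0.0,
    base_quality: int = 30,
) -> SimResult:
    """Emit BID-seq-style alignments: modified molecules delete the target base.

    Modified molecules carry a single-base deletion at the target site with
    probability ``p_del_given_mod``, unmodified with ``p_del_given_unmod``;
    an optional flat background deletion rate applies elsewhere.
    """
    if n_reads < 0:
        raise ConfigError(f"n_reads must be >= 0, got {n_reads}")
    _check_rate(background_del_rate, "background_del_rate")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out_dir}: {exc}") from exc
    fasta_path = ref.write_fasta(out_dir / f"{prefix}.fa")
    bam_path = out_dir / f"{prefix}.bam"
    rng = np.random.default_rng(seed)
    truth_rows: list[tuple[str, str, bool]] = []

    with _open_out_bam(bam_path, ref) as out:
        for tid, (name, seq) in enumerate(ref.records):
            if n_reads == 0:
                continue
            L = len(seq)
            frac = _check_rate(_rate(frac_modified, name, "frac_modified"), "frac_modified")
            p_dm = _check_rate(_rate(p_del_given_mod, name, "p_del_given_mod"), "p_del_given_mod")
            p_du = _check_rate(_rate(p_del_given_unmod, name, "p_del_given_unmod"), "p_del_given_unmod")
            sites = [s.position for s in ref.sites_for(name)]
            true_mod = rng.random(n_reads) < frac
            del_mask = rng.random((n_reads, L)) < background_del_rate
            for pos in sites:
                p_del = np.where(true_mod, p_dm, p_du)
                del_mask[:, pos] = rng.random(n_reads) < p_del
            seq_arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
            pending: list[pysam.AlignedSegment] = []
            for i in range(n_reads):
                read_id = f"{name}_bid{i:06d}"
                truth_rows.append((read_id, name, bool(true_mod[i])))
                offset, cigar, kept = _cigar_from_deletions(del_mask[i])
                if not cigar:
                    continue
                qseq = "".join(seq_arr[kept])
                a = pysam.AlignedSegment(out.header)
                a.query_name = read_id
                a.query_sequence = qseq
                a.flag = 0
                a.reference_id = tid
                a.reference_start = offset
                a.mapping_quality = 60
                a.cigartuples = cigar
                a.query_qualities = pysam.qualitystring_to_array(chr(base_quality + 33) * len(qseq))
                pending.append(a)
            pending.sort(key=lambda r: (r.reference_start, r.query_name))
            for a in pending:
                out.write(a)

    pysam.index(str(bam_path))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "ref_name", "true_modified"])
    truth_path = out_dir / f"{prefix}.truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimResult(bam_path=bam_path, fasta_path=fasta_path, truth_path=truth_path, truth=truth)


# ---------------------------------------------------------------------------
# flow cytometry event simulation
# ---------------------------------------------------------------------------


@dataclass
class FlowSimConfig:
    """Log-normal mixture of cytometry subpopulations.

    ``fractions`` must sum to 1 over the four populations; ``channels`` maps
    population -> channel -> (mu, sigma) of the natural-log intensity.
    """

    n_events: int = 50000
    fractions: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FLOW_FRACTIONS))
    channels: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {p: dict(c) for p, c in DEFAULT_FLOW_CHANNELS.items()}
    )
    doublet_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ConfigError(f"n_events must be >= 0, got {self.n_events}")
        missing = set(FLOW_POPULATIONS) - set(self.fractions)
        if missing:
            raise ConfigError(f"fractions missing populations: {sorted(missing)}")
        total = sum(self.fractions[p] for p in FLOW_POPULATIONS)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"subpopulation fractions sum to {total}, expected 1")
        _check_rate(self.doublet_fraction, "doublet_fraction")
        for pop in FLOW_POPULATIONS:
            for ch in FLOW_CHANNELS:
                try:
                    _, sigma = self.channels[pop][ch]
                except KeyError:
                    raise ConfigError(f"channels missing ({pop!r}, {ch!r})") from None
                if sigma <= 0:
                    raise ConfigError(f"sigma must be > 0 for ({pop}, {ch}), got {sigma}")


def simulate_flow_events(cfg: FlowSimConfig, out_csv: str | Path | None = None) -> pd.DataFrame:
    """Simulate a per-cell event table with known subpopulation labels."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_events
    probs = np.array([cfg.fractions[p] for p in FLOW_POPULATIONS])
    pop_idx = rng.choice(len(FLOW_POPULATIONS), size=n, p=probs)
    data = {"event_id": np.arange(n)}
    for ch in FLOW_CHANNELS:
        values = np.empty(n)
        for k, pop in enumerate(FLOW_POPULATIONS):
            mask = pop_idx == k
            mu, sigma = cfg.channels[pop][ch]
            values[mask] = rng.lognormal(mu, sigma, size=int(mask.sum()))
        data[ch] = values
    df = pd.DataFrame(data)
    df["singlet"] = rng.random(n) >= cfg.doublet_fraction
    df["population"] = pd.Series([FLOW_POPULATIONS[k] for k in pop_idx], dtype="object")
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
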