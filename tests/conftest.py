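"""Shared fixtures: hand-built BAMs, small reference sets, naive oracles."""

from __future__ import annotations

from array import array
from pathlib import Path

import numpy as np
import pysam
import pytest

from oreo import ReferenceSet, TargetSite


def write_bam(
    path: Path,
    references: list[tuple[str, int]],
    reads: list[dict],
) -> Path:
    """Write a sorted+indexed BAM from plain dict read descriptions.

    Each read dict: name, ref (name), start, cigar (pysam tuples), seq,
    quals (list of ints, default 30s), optional tags list of (tag, value, type).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in references],
    }
    tid = {n: i for i, (n, _) in enumerate(references)}
    reads = sorted(reads, key=lambda r: (tid[r["ref"]], r["start"], r["name"]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for r in reads:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = r["name"]
            a.query_sequence = r["seq"]
            a.flag = r.get("flag", 0)
            a.reference_id = tid[r["ref"]]
            a.reference_start = r["start"]
            a.mapping_quality = 60
            a.cigartuples = r["cigar"]
            quals = r.get("quals", [30] * len(r["seq"]))
            a.query_qualities = array("B", quals)
            for tag, value, vtype in r.get("tags", []):
                a.set_tag(tag, value, vtype)
            bam.write(a)
    pysam.index(str(path))
    return path


def naive_pileup_counts(reads: list[dict], ref_len: int, min_base_quality: int = 0):
    """Independent per-read alignment walk; returns per-position counts.

    Counts A/C/G/T calls with quality >= min_base_quality ('N' excluded) and
    deletions regardless of quality. Mirrors the composition contract, not the
    pileup-engine implementation.
    """
    counts = [{b: 0 for b in "ACGT"} | {"deletion": 0} for _ in range(ref_len)]
    for r in reads:
        rpos = r["start"]
        qpos = 0
        quals = r.get("quals", [30] * len(r["seq"]))
        for op, length in r["cigar"]:
            if op in (0, 7, 8):  # aligned
                for k in range(length):
                    base = r["seq"][qpos + k]
                    if base != "N" and quals[qpos + k] >= min_base_quality:
                        counts[rpos + k][base] += 1
                rpos += length
                qpos += length
            elif op == 2:  # deletion
                for k in range(length):
                    counts[rpos + k]["deletion"] += 1
                rpos += length
            elif op == 3:  # refskip
                rpos += length
            elif op in (1, 4):  # insertion / softclip consume query only
                qpos += length
    return counts


def random_instance(rng: np.random.Generator, max_reads: int = 20, max_len: int = 50):
    """Random tiny alignment instance: reference + reads with M/D/I ops,
    occasional 'N' calls and sub-threshold qualities."""
    ref_len = int(rng.integers(10, max_len + 1))
    ref_seq = "".join(rng.choice(list("ACGT"), size=ref_len))
    n_reads = int(rng.integers(1, max_reads + 1))
    reads = []
    for i in range(n_reads):
        start = int(rng.integers(0, ref_len - 4))
        span = int(rng.integers(4, ref_len - start + 1))
        cigar = []
        seq = []
        quals = []
        rpos = start
        end = start + span
        while rpos < end:
            roll = rng.random()
            if roll < 0.15 and cigar and rpos + 1 < end and cigar[-1][0] != 2:
                dlen = int(rng.integers(1, min(3, end - rpos) + 1))
                cigar.append((2, dlen))
                rpos += dlen
                continue
            if roll < 0.25 and cigar and cigar[-1][0] == 0:
                ilen = int(rng.integers(1, 3))
                cigar.append((1, ilen))
                seq.extend(rng.choice(list("ACGT"), size=ilen))
                quals.extend([30] * ilen)
                continue
            mlen = int(rng.integers(1, end - rpos + 1))
            if cigar and cigar[-1][0] == 0:
                cigar[-1] = (0, cigar[-1][1] + mlen)
            else:
                cigar.append((0, mlen))
            for _ in range(mlen):
                if rng.random() < 0.05:
                    seq.append("N")
                    quals.append(30)
                else:
                    base = ref_seq[rpos] if rng.random() < 0.8 else rng.choice(list("ACGT"))
                    seq.append(base)
                    quals.append(int(rng.integers(2, 41)))
                rpos += 1
        # alignments cannot end in D
        if cigar[-1][0] == 2:
            cigar.pop()
        reads.append(
            {
                "name": f"r{i:03d}",
                "ref": "ref",
                "start": start,
                "cigar": cigar,
                "seq": "".join(seq),
                "quals": quals,
            }
        )
    return ref_seq, reads


@pytest.fixture(scope="session")
def tiny_ref() -> ReferenceSet:
    """41-bp single reference with one target uridine at position 20."""
    rng = np.random.default_rng(11)
    left = "".join(rng.choice(list("ACGT"), size=20))
    right = "".join(rng.choice(list("ACGT"), size=20))
    seq = left + "T" + right
    return ReferenceSet(records=[("reporter", seq)], target_sites=[TargetSite("reporter", 20)])


@pytest.fixture(scope="session")
def dual_ref() -> ReferenceSet:
    """Two-reporter reference set mirroring the default scenario layout."""
    from oreo.pipeline import SYNTHETIC_EGFP_MOTIF, SYNTHETIC_MCHERRY_MOTIF
    from oreo import make_reference

    return make_reference(SYNTHETIC_EGFP_MOTIF, SYNTHETIC_MCHERRY_MOTIF, flank_len=50, seed=7)
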