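"""Readers/writers for fragment tables, sample sheets and feature matrices.

Fragment input is either a BED3-style TSV (0-based, half-open; plain or
gzip) or a coordinate-sorted SAM/BAM alignment file, from which one
fragment per properly-paired primary alignment is taken as
[pos, pos + TLEN) on the leftmost mate with positive template length.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_fragments",
    "read_sample_sheet",
    "write_matrix",
    "read_matrix",
    "write_manifest",
    "derive_seed",
]

MAX_TEMPLATE_LENGTH = 1000
MALFORMED_TOLERANCE = 0.01


def _read_fragments_bed(path: Path) -> pd.DataFrame:
    opener = gzip.open if str(path).endswith(".gz") else open
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    malformed = 0
    total = 0
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            total += 1
            parts = line.split("\t")
            try:
                c, s, e = parts[0], int(parts[1]), int(parts[2])
            except (IndexError, ValueError):
                malformed += 1
                continue
            if s < 0 or s >= e:
                malformed += 1
                continue
            chroms.append(c)
            starts.append(s)
            ends.append(e)
    if total and malformed / total > MALFORMED_TOLERANCE:
        raise ValueError(f"{malformed}/{total} malformed rows in {path}")
    if malformed:
        warnings.warn(f"skipped {malformed} malformed rows in {path}")
    return pd.DataFrame(
        {
            "chrom": np.asarray(chroms, dtype=object),
            "start": np.asarray(starts, dtype=np.int64),
            "end": np.asarray(ends, dtype=np.int64),
        }
    )


def _read_fragments_alignment(path: Path) -> pd.DataFrame:
    import pysam

    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode) as af:
        so = (af.header.to_dict().get("HD") or {}).get("SO")
        if so != "coordinate":
            raise ValueError(f"alignment file {path} is not coordinate-sorted (SO={so!r})")
        chroms, starts, ends = [], [], []
        for rec in af:
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or not rec.is_proper_pair
            ):
                continue
            tlen = rec.template_length
            if tlen < 1 or tlen > MAX_TEMPLATE_LENGTH:
                continue  # keep only the leftmost mate (positive TLEN)
            chroms.append(rec.reference_name)
            starts.append(rec.reference_start)
            ends.append(rec.reference_start + tlen)
    return pd.DataFrame(
        {
            "chrom": np.asarray(chroms, dtype=object),
            "start": np.asarray(starts, dtype=np.int64),
            "end": np.asarray(ends, dtype=np.int64),
        }
    )


def read_fragments(path) -> pd.DataFrame:
    """Read a per-sample fragment table (chrom, start, end)."""
    p = Path(path)
    if p.suffix in {".bam", ".sam"} or p.name.endswith((".bam", ".sam")):
        return _read_fragments_alignment(p)
    return _read_fragments_bed(p)


def read_sample_sheet(path, fragments_root=None) -> pd.DataFrame:
    """Read and validate the cohort sample sheet CSV.

    Required columns: sample_id, label, psa_ng_ml; optional: stage,
    gleason, isup, fragments_path (resolved relative to
    ``fragments_root`` or the sheet's directory).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str})
    for col in ("sample_id", "label", "psa_ng_ml"):
        if col not in df.columns:
            raise ValueError(f"sample sheet missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    bad = ~df["label"].isin(["cancer", "non-cancer"])
    if bad.any():
        raise ValueError(f"invalid labels: {df.loc[bad, 'label'].unique().tolist()}")
    psa = pd.to_numeric(df["psa_ng_ml"], errors="coerce")
    if (psa <= 0).any():
        raise ValueError("psa_ng_ml must be positive (or missing)")
    df["psa_ng_ml"] = psa
    if "fragments_path" in df.columns:
        root = Path(fragments_root) if fragments_root is not None else path.parent
        df["fragments_path"] = [str(root / p) for p in df["fragments_path"]]
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a samples-by-features matrix TSV at full round-trip precision."""
    df.to_csv(path, sep="\t", index_label="sample_id", float_format="%.17g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id", float_precision="round_trip")


def write_manifest(path, config: dict, seed: int, inputs: dict[str, str] | None = None) -> None:
    """Write a JSON run manifest (config snapshot, seed, input checksums)."""
    checksums = {}
    for name, p in (inputs or {}).items():
        h = hashlib.sha256()
        with open(p, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        checksums[name] = h.hexdigest()
    payload = {"config": config, "seed": seed, "input_sha256": checksums}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def derive_seed(master: int, *tokens) -> int:
    """Deterministically derive a sub-seed (< 2**31) from a master seed.

    String tokens are hashed through CRC32 so the derivation is stable
    across sessions and platforms.
    """
    import zlib

    ints = [int(t) if not isinstance(t, str) else zlib.crc32(t.encode()) for t in tokens]
    ss = np.random.SeedSequence([int(master), *ints])
    return int(ss.generate_state(1)[0] % (2**31))
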