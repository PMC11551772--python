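"""File formats: bedGraph, GenBank/YAML replicon metadata, TSV/JSON output.

All genomic coordinates are 0-based half-open internally; GenBank's
1-based closed coordinates are converted at the boundary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .genome import Replicon
from .mfa import MFAProfile, ReplicationFit, WindowCounts

__all__ = [
    "read_bedgraph",
    "to_window_counts",
    "write_bedgraph",
    "read_genbank_metadata",
    "read_genome_yaml",
    "write_profile_tsv",
    "read_profile_tsv",
    "write_fit_json",
    "sha256_of",
]

_SKIP_PREFIXES = ("track", "browser", "#")


def read_bedgraph(path, replicons: list[Replicon]) -> pd.DataFrame:
    """Parse a 4-column bedGraph into a validated interval table.

    Track/browser/comment lines are skipped.  Unknown replicon names are
    rejected with a listing of the known ones; negative counts and
    overlapping intervals are errors (reported with the offending line).
    An interval running past the end of a circular replicon is split at
    the boundary and wrapped.
    """
    known = {r.name: r for r in replicons}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            name, s, e, c = parts
            if name not in known:
                raise ValueError(
                    f"{path}:{lineno}: unknown replicon {name!r}; "
                    f"known: {sorted(known)}"
                )
            try:
                s, e, c = int(s), int(e), float(c)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
            if c < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if not 0 <= s < e:
                raise ValueError(f"{path}:{lineno}: bad interval [{s}, {e})")
            rep = known[name]
            if e > rep.length_bp:
                if not rep.circular or s >= rep.length_bp:
                    raise ValueError(
                        f"{path}:{lineno}: interval exceeds replicon length"
                    )
                # split at the circular boundary, count apportioned by length
                total = e - s
                left = rep.length_bp - s
                rows.append((name, s, rep.length_bp, c * left / total))
                rows.append((name, 0, e - rep.length_bp, c * (e - rep.length_bp) / total))
            else:
                rows.append((name, s, e, c))
    df = pd.DataFrame(rows, columns=["replicon", "start", "end", "count"])
    for name, sub in df.groupby("replicon"):
        sub = sub.sort_values("start")
        if np.any(sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]):
            raise ValueError(f"{path}: overlapping intervals on replicon {name!r}")
    return df.sort_values(["replicon", "start"], kind="stable").reset_index(drop=True)


def to_window_counts(
    intervals: pd.DataFrame,
    replicons: list[Replicon],
    window_bp: int,
    phase: str = "exponential",
) -> WindowCounts:
    """Bin an interval table onto a uniform window grid.

    Intervals must either align with the grid (one interval per window)
    or be sub-window-sized (per-base style), in which case counts are
    accumulated into the containing window.  Intervals straddling a
    window boundary without covering whole windows are rejected.
    """
    from .genome import tile_windows

    frames = []
    for rep in replicons:
        starts, ends = tile_windows(rep.length_bp, window_bp)
        acc = np.zeros(starts.size, dtype=float)
        sub = intervals[intervals["replicon"] == rep.name]
        for s, e, c in zip(sub["start"], sub["end"], sub["count"]):
            i0, i1 = s // window_bp, (e - 1) // window_bp
            if i0 == i1:
                acc[i0] += c
            elif s % window_bp == 0 and (e % window_bp == 0 or e == rep.length_bp):
                # aligned multi-window interval: spread count per bp
                per_bp = c / (e - s)
                for i in range(i0, i1 + 1):
                    lo = max(s, int(starts[i]))
                    hi = min(e, int(ends[i]))
                    acc[i] += per_bp * (hi - lo)
            else:
                raise ValueError(
                    f"interval [{s}, {e}) on {rep.name!r} straddles the "
                    f"{window_bp} bp grid; re-bin the input"
                )
        frames.append(
            pd.DataFrame(
                {
                    "replicon": rep.name,
                    "start": starts,
                    "end": ends,
                    "count": np.rint(acc).astype(np.int64),
                }
            )
        )
    return WindowCounts(pd.concat(frames, ignore_index=True), window_bp, phase)


def write_bedgraph(counts: WindowCounts, path) -> None:
    with open(path, "w") as fh:
        for row in counts.df.itertuples(index=False):
            fh.write(f"{row.replicon}\t{row.start}\t{row.end}\t{row.count}\n")


def read_alignment_starts(path) -> dict[str, np.ndarray]:
    """Thin optional extractor of read-start positions from SAM/BAM.

    Returns a mapping of reference name to 0-based leftmost mapped
    positions of primary, mapped alignments — the per-base input of
    :func:`replidose.mfa.aggregate_windows`.  Requires ``pysam``
    (install the ``bam`` extra); everything downstream of counting
    works from bedGraph text and does not need it.
    """
    import pysam  # deferred: optional dependency

    starts: dict[str, list[int]] = {}
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            starts.setdefault(aln.reference_name, []).append(aln.reference_start)
    return {k: np.asarray(v, dtype=np.int64) for k, v in starts.items()}


# ---------------------------------------------------------------------------
# replicon metadata


def read_genbank_metadata(
    path, ori_override: dict[str, int] | None = None
) -> list[Replicon]:
    """Extract replicon lengths and annotated origins from GenBank.

    The origin is taken from the first ``rep_origin`` feature, or from
    any feature whose ``note``/``standard_name`` mentions ``oriC``.
    ``ori_override`` (name -> position, 0-based) wins over annotation.
    """
    ori_override = ori_override or {}
    reps = []
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ValueError(f"{path}: no GenBank records")
    for rec in records:
        ori = None
        for feat in rec.features:
            quals = " ".join(
                " ".join(feat.qualifiers.get(k, []))
                for k in ("note", "standard_name", "gene")
            ).lower()
            if feat.type == "rep_origin" or "oric" in quals:
                ori = int(feat.location.start)  # Biopython is already 0-based
                break
        circular = rec.annotations.get("topology", "circular") == "circular"
        name = rec.id or rec.name
        if name in ori_override:
            ori = int(ori_override[name])
        reps.append(Replicon(name, len(rec.seq), circular, ori))
    return reps


def read_genome_yaml(path) -> list[Replicon]:
    """Replicon metadata from YAML: a list of mappings with keys
    ``name, length_bp, circular, ori_bp, ter_bp``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict):
        raw = raw.get("replicons", [])
    return [
        Replicon(
            r["name"],
            int(r["length_bp"]),
            bool(r.get("circular", True)),
            r.get("ori_bp"),
            r.get("ter_bp"),
        )
        for r in raw
    ]


# ---------------------------------------------------------------------------
# results


def write_profile_tsv(profile: MFAProfile, path) -> None:
    df = profile.df.copy()
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_profile_tsv(path, window_bp: int) -> MFAProfile:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["nan", ""])
    df["reason"] = df["reason"].fillna("").astype(str)
    return MFAProfile(df, window_bp)


def write_fit_json(fit: ReplicationFit, path, extra: dict | None = None) -> None:
    payload = {
        "replicons": {name: asdict(f) for name, f in fit.replicons.items()},
        "primary": fit.primary,
        "secondary": fit.secondary,
        "initiation_delay_log2": fit.initiation_delay_log2,
        "initiation_delay_min": fit.initiation_delay_min,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
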