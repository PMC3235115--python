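"""Window datasets for internal pyroglutamate (PCA) site prediction.

A candidate site is a glutamine (Q) in the internal region of a protein.
Each site is represented by a 21-residue peptide fragment: the candidate
residue at window site 11 plus 10 residues upstream and 10 downstream.
Fragments running off either end of the protein are padded with ``'-'``.
Positive fragments come from annotated modification sites; negatives are
drawn uniformly without replacement from the remaining internal Q sites at
a fixed positive:negative ratio (default 1:5).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
PAD = "-"
POSITIVE = "positive"
NEGATIVE = "negative"

#: Default number of residues on each side of the candidate site.
DEFAULT_FLANK = 10

#: First residue position (1-based) counted as "internal"; position 1 is
#: the N-terminus, which follows a distinct chemistry and is excluded.
DEFAULT_MIN_INTERNAL_POS = 2


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-length peptide fragment centered on a candidate site.

    Attributes
    ----------
    protein_id : str
        Identifier of the source protein.
    center_pos : int
        1-based residue position of the candidate site in the protein.
    residues : str
        Window string over the 20 amino-acid letters plus ``'-'`` pads;
        pads occur only as a contiguous prefix and/or suffix.
    label : str
        ``"positive"`` (annotated modification site) or ``"negative"``.
    """

    protein_id: str
    center_pos: int
    residues: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")
        core = self.residues.strip(PAD)
        if PAD in core:
            raise ValueError(
                f"pads must be a contiguous prefix/suffix: {self.residues!r}"
            )
        bad = set(core) - set(AA_ALPHABET)
        if bad:
            raise ValueError(f"unknown residue letters {sorted(bad)} in window")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SiteAnnotation:
    """One annotated modification site: protein, 1-based position, residue."""

    protein_id: str
    position: int
    residue: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    def is_internal(self, min_pos: int = DEFAULT_MIN_INTERNAL_POS) -> bool:
        return self.position >= min_pos


def extract_window(sequence: str, center: int, flank: int = DEFAULT_FLANK) -> str:
    """Extract a ``2*flank + 1`` residue window centered on ``center``.

    Positions outside the sequence are filled with ``'-'``.

    Parameters
    ----------
    sequence : str
        Protein sequence (1-letter codes).
    center : int
        1-based position of the candidate residue.
    flank : int
        Number of residues to include on each side.

    Returns
    -------
    str
        Window of length ``2*flank + 1`` with ``sequence[center]`` at the
        middle position.
    """
    n = len(sequence)
    if not 1 <= center <= n:
        raise ValueError(
            f"center position {center} outside sequence of length {n}"
        )
    lo = center - 1 - flank  # 0-based inclusive
    hi = center + flank  # 0-based exclusive
    left_pad = max(0, -lo)
    right_pad = max(0, hi - n)
    return PAD * left_pad + sequence[max(lo, 0) : min(hi, n)] + PAD * right_pad


def build_positive_set(
    sequences: Mapping[str, str],
    annotations: Iterable[SiteAnnotation],
    flank: int = DEFAULT_FLANK,
    min_internal_pos: int = DEFAULT_MIN_INTERNAL_POS,
) -> list[PeptideWindow]:
    """Build the positive window set from annotated internal sites.

    One window is extracted per internal annotation; windows with an
    identical residue string are collapsed, keeping the first occurrence
    in input order.
    """
    windows: list[PeptideWindow] = []
    seen: set[str] = set()
    for ann in annotations:
        if not ann.is_internal(min_internal_pos):
            continue
        if ann.protein_id not in sequences:
            raise KeyError(
                f"annotation references unknown protein {ann.protein_id!r}"
            )
        seq = sequences[ann.protein_id]
        if not 1 <= ann.position <= len(seq):
            raise ValueError(
                f"annotated position {ann.position} outside protein "
                f"{ann.protein_id!r} of length {len(seq)}"
            )
        observed = seq[ann.position - 1]
        if observed != ann.residue:
            raise ValueError(
                f"annotation residue {ann.residue!r} does not match sequence "
                f"residue {observed!r} at {ann.protein_id!r}:{ann.position}"
            )
        frag = extract_window(seq, ann.position, flank)
        if frag in seen:
            continue
        seen.add(frag)
        windows.append(
            PeptideWindow(ann.protein_id, ann.position, frag, POSITIVE)
        )
    return windows


def build_negative_set(
    sequences: Mapping[str, str],
    positive_windows: Sequence[PeptideWindow],
    target_residue: str = "Q",
    ratio: int = 5,
    seed: int = 0,
    flank: int = DEFAULT_FLANK,
    min_internal_pos: int = DEFAULT_MIN_INTERNAL_POS,
) -> list[PeptideWindow]:
    """Sample negative windows from unannotated internal target residues.

    The candidate pool is every internal occurrence of ``target_residue``
    whose window string differs from all positive windows and from every
    earlier candidate (full-window identity).  Exactly
    ``ratio * len(positive_windows)`` candidates are drawn uniformly
    without replacement; the draw is deterministic for a fixed ``seed``.
    """
    if ratio < 1:
        raise ValueError(f"ratio must be a positive integer, got {ratio}")
    positive_frags = {w.residues for w in positive_windows}
    pool: list[PeptideWindow] = []
    seen: set[str] = set()
    for pid in sequences:
        seq = sequences[pid]
        for pos0, letter in enumerate(seq):
            pos = pos0 + 1
            if letter != target_residue or pos < min_internal_pos:
                continue
            frag = extract_window(seq, pos, flank)
            if frag in positive_frags or frag in seen:
                continue
            seen.add(frag)
            pool.append(PeptideWindow(pid, pos, frag, NEGATIVE))
    n_needed = ratio * len(positive_windows)
    if len(pool) < n_needed:
        raise ValueError(
            f"negative candidate pool has {len(pool)} windows, "
            f"{n_needed} requested"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n_needed, replace=False)
    return [pool[i] for i in sorted(idx)]


def position_frequencies(
    windows: Sequence[PeptideWindow],
) -> pd.DataFrame:
    """Per-site amino-acid frequencies over a window set.

    Returns a (window length) x 20 table of relative frequencies, the
    numeric content of a sequence logo.  Pads are excluded from the
    per-site denominator.
    """
    if not windows:
        raise ValueError("no windows given")
    length = len(windows[0].residues)
    counts = np.zeros((length, len(AA_ALPHABET)), dtype=float)
    col = {aa: j for j, aa in enumerate(AA_ALPHABET)}
    for w in windows:
        for i, letter in enumerate(w.residues):
            if letter != PAD:
                counts[i, col[letter]] += 1.0
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.0)
    return pd.DataFrame(
        freqs, index=range(1, length + 1), columns=list(AA_ALPHABET)
    )


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences from FASTA into an id -> sequence mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_sites_tsv(path: str | Path) -> list[SiteAnnotation]:
    """Read site annotations from TSV (protein_id, position, residue)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "residue": str})
    required = {"protein_id", "position", "residue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sites file {path} missing columns {sorted(missing)}")
    return [
        SiteAnnotation(row.protein_id, int(row.position), row.residue)
        for row in df.itertuples(index=False)
    ]


def write_windows_tsv(windows: Sequence[PeptideWindow], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "protein_id": [w.protein_id for w in windows],
            "center_pos": [w.center_pos for w in windows],
            "residues": [w.residues for w in windows],
            "label": [w.label for w in windows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_windows_tsv(path: str | Path) -> list[PeptideWindow]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        PeptideWindow(r.protein_id, int(r.center_pos), r.residues, r.label)
        for r in df.itertuples(index=False)
    ]
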