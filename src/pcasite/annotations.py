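"""Per-residue annotation tracks and per-amino-acid property tables.

Four per-residue tracks feed the window encoder:

* PSSM conservation scores — one 20-vector per residue, parsed from the
  PSI-BLAST ASCII profile dialect (``-Q`` output);
* a disorder propensity score in [0, 1];
* a 3-state secondary-structure call (helix / strand / other);
* a 2-state solvent-accessibility call (buried / exposed).

Five per-amino-acid property tables are embedded: the Atchley five-factor
physicochemical summary scores, an evolutionary gain/loss index, two
conservation propensities (protein-protein interface, protein surface) and
the side-chain carbon atom count.  All single-valued tables can be
overridden from CSV; the carbon counts are chemical constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import AA_ALPHABET, PAD, POSITIVE, PeptideWindow

SS_CLASSES = ("helix", "strand", "other")
ACC_CLASSES = ("buried", "exposed")

#: Column order of the PSI-BLAST ASCII PSSM score block.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"

# ---------------------------------------------------------------------------
# Embedded per-amino-acid tables

#: Atchley et al. five-factor solution summarizing ~500 AAIndex properties.
#: Factor order: polarity, secondary structure, molecular volume,
#: codon diversity, electrostatic charge.
ATCHLEY_FACTORS: dict[str, tuple[float, float, float, float, float]] = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}

FACTOR_NAMES = (
    "Polarity",
    "Secondary Structure",
    "Molecular Volume",
    "Codon Diversity",
    "Electrostatic Charge",
)

#: Net gain/loss index of each amino acid over protein evolution
#: (positive = net gainer: C, M, H, S, F; negative = net loser: P, A, G, E).
#: Signed, zero-centered defaults reflecting the reported trend; overridable.
GAIN_LOSS: dict[str, float] = {
    "A": -0.52, "C": 0.65, "D": -0.10, "E": -0.32, "F": 0.28,
    "G": -0.45, "H": 0.38, "I": 0.22, "K": 0.10, "L": 0.05,
    "M": 0.48, "N": 0.12, "P": -0.60, "Q": -0.05, "R": 0.18,
    "S": 0.32, "T": 0.08, "V": 0.02, "W": -0.08, "Y": -0.02,
}

#: Propensity to be conserved at protein-protein interaction interfaces
#: (hydrophobic/aromatic residues enriched); overridable defaults.
INTERFACE_PROPENSITY: dict[str, float] = {
    "A": 0.17, "C": 0.43, "D": 0.25, "E": 0.16, "F": 0.55,
    "G": 0.20, "H": 0.40, "I": 0.44, "K": 0.12, "L": 0.40,
    "M": 0.47, "N": 0.28, "P": 0.25, "Q": 0.22, "R": 0.33,
    "S": 0.21, "T": 0.24, "V": 0.38, "W": 0.58, "Y": 0.50,
}

#: Propensity to be conserved on the solvent-exposed protein surface
#: (polar/charged residues enriched); overridable defaults.
SURFACE_PROPENSITY: dict[str, float] = {
    "A": 0.20, "C": 0.26, "D": 0.42, "E": 0.38, "F": 0.22,
    "G": 0.33, "H": 0.35, "I": 0.16, "K": 0.36, "L": 0.18,
    "M": 0.21, "N": 0.40, "P": 0.36, "Q": 0.35, "R": 0.39,
    "S": 0.37, "T": 0.34, "V": 0.17, "W": 0.28, "Y": 0.30,
}

#: Number of carbon atoms in each side chain (chemical constants; Gly has
#: only a hydrogen side chain).
SIDE_CHAIN_CARBONS: dict[str, int] = {
    "G": 0, "A": 1, "S": 1, "C": 1, "T": 2, "N": 2, "D": 2,
    "V": 3, "P": 3, "M": 3, "Q": 3, "E": 3,
    "L": 4, "I": 4, "K": 4, "R": 4, "H": 4,
    "F": 7, "Y": 7, "W": 9,
}


@dataclass(frozen=True)
class ResidueProfile:
    """All per-residue annotations needed to encode one window position."""

    pssm_row: tuple[float, ...]
    disorder: float
    ss_class: str
    acc_class: str

    def __post_init__(self) -> None:
        if len(self.pssm_row) != 20:
            raise ValueError(f"pssm_row must have 20 entries, got {len(self.pssm_row)}")
        if self.ss_class not in SS_CLASSES:
            raise ValueError(f"unknown secondary-structure class {self.ss_class!r}")
        if self.acc_class not in ACC_CLASSES:
            raise ValueError(f"unknown accessibility class {self.acc_class!r}")


@dataclass(frozen=True)
class PropertyTables:
    """Per-amino-acid lookup tables used by the encoder."""

    aa_factors: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(ATCHLEY_FACTORS)
    )
    gain_loss: Mapping[str, float] = field(default_factory=lambda: dict(GAIN_LOSS))
    interface_propensity: Mapping[str, float] = field(
        default_factory=lambda: dict(INTERFACE_PROPENSITY)
    )
    surface_propensity: Mapping[str, float] = field(
        default_factory=lambda: dict(SURFACE_PROPENSITY)
    )
    side_chain_carbons: Mapping[str, int] = field(
        default_factory=lambda: dict(SIDE_CHAIN_CARBONS)
    )

    def __post_init__(self) -> None:
        for name in (
            "aa_factors",
            "gain_loss",
            "interface_propensity",
            "surface_propensity",
            "side_chain_carbons",
        ):
            table = getattr(self, name)
            missing = sorted(set(AA_ALPHABET) - set(table))
            if missing:
                raise ValueError(f"table {name!r} missing amino acids {missing}")

    @property
    def mean_side_chain_carbons(self) -> float:
        """Mean carbon count over the 20 amino acids; used for '-' pads."""
        return float(np.mean([self.side_chain_carbons[a] for a in AA_ALPHABET]))


def load_property_tables(
    overrides: Mapping[str, Mapping[str, float]] | None = None,
) -> PropertyTables:
    """Build the property tables, optionally overriding any of them.

    ``overrides`` maps a table name (``gain_loss``, ``interface_propensity``,
    ``surface_propensity``, ``side_chain_carbons``, ``aa_factors``) to a
    replacement per-amino-acid mapping; each table must cover all 20
    standard amino acids.
    """
    kwargs: dict = {}
    if overrides:
        unknown = set(overrides) - {
            "aa_factors",
            "gain_loss",
            "interface_propensity",
            "surface_propensity",
            "side_chain_carbons",
        }
        if unknown:
            raise ValueError(f"unknown property tables {sorted(unknown)}")
        kwargs.update({k: dict(v) for k, v in overrides.items()})
    return PropertyTables(**kwargs)


def read_property_csv(path: str | Path) -> dict[str, float]:
    """Read a single-valued table override: CSV with columns letter,value."""
    df = pd.read_csv(path, dtype={0: str})
    letters = df.iloc[:, 0].astype(str)
    values = df.iloc[:, 1].astype(float)
    return dict(zip(letters, values))


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM

_PSSM_HEADER = (
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative "
    "weight of gapless real matches to pseudocounts"
)


@dataclass(frozen=True)
class Pssm:
    """One protein's PSSM: residue letters and an L x 20 log-odds matrix.

    Columns are ordered by the package alphabet (alphabetical one-letter
    codes), regardless of the on-disk column order.
    """

    residues: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.residues), 20):
            raise ValueError(
                f"scores shape {self.scores.shape} does not match "
                f"{len(self.residues)} residues x 20"
            )


def read_pssm(path: str | Path) -> Pssm:
    """Parse a PSI-BLAST ASCII PSSM file (the ``-Q`` dialect).

    Only the first 20 numeric columns of each residue row (the log-odds
    block) are used.  Column order is normalized to the package's
    alphabetical amino-acid order.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    order = PSIBLAST_ORDER
    rows: list[list[int]] = []
    letters: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        # Header line listing the column amino acids (>= 20 single letters).
        if all(len(t) == 1 and t.isalpha() for t in tokens) and len(tokens) >= 20:
            order = "".join(tokens[:20])
            continue
        if not tokens[0].isdigit():
            continue  # title / footer lines
        if len(tokens) < 22:
            raise ValueError(
                f"{path}:{lineno}: expected residue letter + 20 score "
                f"columns, found {len(tokens) - 2} score fields"
            )
        letter = tokens[1]
        try:
            scores = [int(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer score field") from exc
        letters.append(letter)
        rows.append(scores)
    if not rows:
        raise ValueError(f"{path}: no PSSM rows found")
    raw = np.asarray(rows, dtype=float)
    # reorder columns from file order to the package alphabet
    col = [order.index(a) for a in AA_ALPHABET]
    return Pssm("".join(letters), raw[:, col])


def write_pssm(pssm: Pssm, path: str | Path) -> None:
    """Write a PSSM in the PSI-BLAST ASCII dialect read by :func:`read_pssm`.

    The percentage block is filled with zeros; only the log-odds block
    carries information, matching what the parser consumes.
    """
    # back to PSI-BLAST column order for the on-disk representation
    col = [AA_ALPHABET.index(a) for a in PSIBLAST_ORDER]
    scores = pssm.scores[:, col]
    out = ["", _PSSM_HEADER]
    out.append(
        "            "
        + "  ".join(PSIBLAST_ORDER)
        + "   "
        + "  ".join(PSIBLAST_ORDER)
    )
    for i, (letter, row) in enumerate(zip(pssm.residues, scores), start=1):
        cells = " ".join(f"{int(v):3d}" for v in row)
        pct = " ".join("  0" for _ in range(20))
        out.append(f"{i:5d} {letter} {cells}  {pct}  0.00 0.00")
    out.append("")
    Path(path).write_text("\n".join(out))


# ---------------------------------------------------------------------------
# Disorder / secondary structure / accessibility tracks (TSV)


def read_track_tsv(path: str | Path) -> dict[str, dict[int, str]]:
    """Read a per-residue track: TSV with columns protein_id, position, value.

    Values are returned as strings; numeric tracks (disorder) should be
    converted by the caller.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "value": str})
    required = {"protein_id", "position", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track file {path} missing columns {sorted(missing)}")
    track: dict[str, dict[int, str]] = {}
    for row in df.itertuples(index=False):
        track.setdefault(row.protein_id, {})[int(row.position)] = row.value
    return track


def profiles_for_window(
    window: PeptideWindow,
    pssms: Mapping[str, Pssm],
    disorder: Mapping[str, Mapping[int, str]],
    ss: Mapping[str, Mapping[int, str]],
    acc: Mapping[str, Mapping[int, str]],
    flank: int | None = None,
) -> list[ResidueProfile | None]:
    """Assemble one :class:`ResidueProfile` per window position.

    Pad positions yield ``None``.  Raises ``KeyError`` naming the protein
    if any track lacks the protein or a needed position.
    """
    length = len(window.residues)
    if flank is None:
        flank = (length - 1) // 2
    pid = window.protein_id
    if pid not in pssms:
        raise KeyError(f"no PSSM available for protein {pid!r}")
    pssm = pssms[pid]
    profiles: list[ResidueProfile | None] = []
    for offset in range(-flank, flank + 1):
        i = flank + offset
        if window.residues[i] == PAD:
            profiles.append(None)
            continue
        pos = window.center_pos + offset  # 1-based position in protein
        try:
            row = tuple(float(v) for v in pssm.scores[pos - 1])
            dis = float(disorder[pid][pos])
            ssc = str(ss[pid][pos])
            accc = str(acc[pid][pos])
        except (KeyError, IndexError) as exc:
            raise KeyError(
                f"missing annotation for protein {pid!r} position {pos}"
            ) from exc
        profiles.append(ResidueProfile(row, dis, ssc, accc))
    return profiles


def synthesize_profiles(
    windows: Sequence[PeptideWindow],
    seed: int,
    bias: float = 0.0,
    informative_sites: Sequence[int] = (),
) -> list[list[ResidueProfile | None]]:
    """Draw synthetic annotation profiles for a window set.

    Each non-pad position receives a PSSM row of small integers
    (discrete, like real log-odds), a disorder score in [0, 1] and
    categorical secondary-structure / accessibility calls.  With
    ``bias > 0``, positions whose 1-based window site is listed in
    ``informative_sites`` are shifted for positive-labelled windows:
    the PSSM row mean and disorder score increase, and the helix /
    exposed categories become more likely.  ``bias = 0`` makes every
    marginal label-independent.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    informative = set(informative_sites)
    out: list[list[ResidueProfile | None]] = []
    for w in windows:
        shifted = w.label == POSITIVE
        profs: list[ResidueProfile | None] = []
        for i, letter in enumerate(w.residues):
            if letter == PAD:
                profs.append(None)
                continue
            site = i + 1
            hot = shifted and site in informative
            shift = bias if hot else 0.0
            row = rng.integers(-5, 8, size=20).astype(float)
            if shift:
                row = row + np.round(shift)
            dis = float(np.clip(rng.uniform(0.0, 1.0) + 0.15 * shift, 0.0, 1.0))
            p_helix = min(0.85, 1.0 / 3.0 + 0.15 * shift)
            rest = (1.0 - p_helix) / 2.0
            ssc = rng.choice(SS_CLASSES, p=[p_helix, rest, rest])
            p_exposed = min(0.9, 0.5 + 0.1 * shift)
            accc = rng.choice(ACC_CLASSES, p=[1.0 - p_exposed, p_exposed])
            profs.append(ResidueProfile(tuple(row), dis, str(ssc), str(accc)))
        out.append(profs)
    return out
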