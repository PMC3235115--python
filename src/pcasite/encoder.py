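"""Canonical feature schema and numeric encoding of peptide windows.

Each of the 21 window sites contributes up to 35 features drawn from 7
property families:

* 20 PSSM conservation scores (one per amino acid),
* 5 Atchley amino-acid factors,
* 1 disorder score,
* 3 one-hot secondary-structure indicators (helix / strand / other),
* 2 one-hot solvent-accessibility indicators (buried / exposed),
* 2 conservation propensities (interface, surface),
* 1 evolutionary gain/loss index,
* 1 deviation of the side-chain carbon count from the window mean.

The center site always holds the candidate residue (Q for real data), so
its residue-identity families (AAFactor, interface/surface, gain/loss)
carry no information and are omitted: 27 features at the center, 35 at
each flanking site, 35*20 + 27 = 727 in total at the default flank of 10.

Pad positions ('-') contribute 0 to every feature except the carbon
deviation, where a pad counts as the mean side-chain carbon number of
the 20 amino acids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import (
    ACC_CLASSES,
    FACTOR_NAMES,
    SS_CLASSES,
    PropertyTables,
    ResidueProfile,
)
from .dataset import AA_ALPHABET, PAD, POSITIVE, PeptideWindow

FAMILY_PSSM = "PSSM"
FAMILY_AAFACTOR = "AAFactor"
FAMILY_DISORDER = "Disorder"
FAMILY_SS = "SecondaryStructure"
FAMILY_ACC = "Accessibility"
FAMILY_INTERFACE_SURFACE = "InterfaceSurface"
FAMILY_GAINLOSS = "GainLoss"
FAMILY_CARBON = "CarbonDeviation"

FAMILIES = (
    FAMILY_PSSM,
    FAMILY_AAFACTOR,
    FAMILY_DISORDER,
    FAMILY_SS,
    FAMILY_ACC,
    FAMILY_INTERFACE_SURFACE,
    FAMILY_GAINLOSS,
    FAMILY_CARBON,
)


@dataclass(frozen=True)
class FeatureDescriptor:
    """One feature column: window site, property family and sub-name."""

    site: int
    family: str
    subname: str

    @property
    def name(self) -> str:
        """Render the conventional column name, e.g. ``AA10-Pssm_A``."""
        prefix = f"AA{self.site}-"
        if self.family == FAMILY_PSSM:
            return f"{prefix}Pssm_{self.subname}"
        if self.family == FAMILY_AAFACTOR:
            return f"{prefix}{self.subname}"
        if self.family == FAMILY_DISORDER:
            return f"{prefix}Disorder"
        if self.family == FAMILY_SS:
            return f"{prefix}Secondary Structure {self.subname.capitalize()}"
        if self.family == FAMILY_ACC:
            return f"{prefix}Accessibility {self.subname.capitalize()}"
        if self.family == FAMILY_INTERFACE_SURFACE:
            return f"{prefix}{self.subname} Propensity"
        if self.family == FAMILY_GAINLOSS:
            return f"{prefix}Gain/Loss"
        if self.family == FAMILY_CARBON:
            return f"{prefix}Side Chain Count of Atom_C Deviation from Mean"
        raise ValueError(f"unknown family {self.family!r}")


class FeatureSchema:
    """Ordered, immutable list of feature descriptors for a given flank."""

    def __init__(self, descriptors: Sequence[FeatureDescriptor], flank: int):
        self.descriptors: tuple[FeatureDescriptor, ...] = tuple(descriptors)
        self.flank = flank

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    def __getitem__(self, i: int) -> FeatureDescriptor:
        return self.descriptors[i]

    @property
    def window_length(self) -> int:
        return 2 * self.flank + 1

    @property
    def center_site(self) -> int:
        return self.flank + 1

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def site_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {s: 0 for s in range(1, self.window_length + 1)}
        for d in self.descriptors:
            counts[d.site] += 1
        return counts

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {f: 0 for f in FAMILIES}
        for d in self.descriptors:
            counts[d.family] += 1
        return counts


def build_schema(flank: int = 10) -> FeatureSchema:
    """Build the canonical feature schema for a window of ``2*flank + 1``.

    Sites run ascending; within a site the family order is PSSM
    (alphabetical amino acids), AAFactor, Disorder, SecondaryStructure
    (helix/strand/other), Accessibility (buried/exposed),
    InterfaceSurface, GainLoss, CarbonDeviation.  The center site omits
    AAFactor, InterfaceSurface and GainLoss.  The ordering is a pure
    function of ``flank``.
    """
    if flank < 0:
        raise ValueError("flank must be nonnegative")
    center = flank + 1
    descriptors: list[FeatureDescriptor] = []
    for site in range(1, 2 * flank + 2):
        for aa in AA_ALPHABET:
            descriptors.append(FeatureDescriptor(site, FAMILY_PSSM, aa))
        if site != center:
            for factor in FACTOR_NAMES:
                descriptors.append(FeatureDescriptor(site, FAMILY_AAFACTOR, factor))
        descriptors.append(FeatureDescriptor(site, FAMILY_DISORDER, "score"))
        for cls in SS_CLASSES:
            descriptors.append(FeatureDescriptor(site, FAMILY_SS, cls))
        for cls in ACC_CLASSES:
            descriptors.append(FeatureDescriptor(site, FAMILY_ACC, cls))
        if site != center:
            descriptors.append(
                FeatureDescriptor(site, FAMILY_INTERFACE_SURFACE, "Interface")
            )
            descriptors.append(
                FeatureDescriptor(site, FAMILY_INTERFACE_SURFACE, "Surface")
            )
            descriptors.append(FeatureDescriptor(site, FAMILY_GAINLOSS, "index"))
        descriptors.append(FeatureDescriptor(site, FAMILY_CARBON, "deviation"))
    return FeatureSchema(descriptors, flank)


def carbon_deviation(window: str, tables: PropertyTables) -> np.ndarray:
    """Side-chain carbon count of each residue minus the window mean.

    Pads count as the mean carbon number over the 20 amino acids, so an
    all-pad window deviates nowhere.  The returned values sum to zero.
    """
    pad_count = tables.mean_side_chain_carbons
    counts = np.empty(len(window), dtype=float)
    for i, letter in enumerate(window):
        if letter == PAD:
            counts[i] = pad_count
        else:
            try:
                counts[i] = tables.side_chain_carbons[letter]
            except KeyError:
                raise ValueError(f"unknown residue letter {letter!r}") from None
    return counts - counts.mean()


def encode(
    window: PeptideWindow,
    profiles: Sequence[ResidueProfile | None],
    tables: PropertyTables,
    schema: FeatureSchema,
) -> np.ndarray:
    """Encode one window into a numeric vector following ``schema``.

    ``profiles`` holds one :class:`ResidueProfile` per window position
    (``None`` at pads).  A pure function: identical inputs give
    bitwise-identical output.
    """
    length = schema.window_length
    if len(window.residues) != length:
        raise ValueError(
            f"window length {len(window.residues)} does not match schema "
            f"window length {length}"
        )
    if len(profiles) != length:
        raise ValueError(
            f"got {len(profiles)} profiles for a {length}-residue window"
        )
    for i, (letter, prof) in enumerate(zip(window.residues, profiles)):
        if letter != PAD and prof is None:
            raise ValueError(f"missing profile at non-pad window site {i + 1}")
    carbon = carbon_deviation(window.residues, tables)
    vec = np.zeros(len(schema), dtype=float)
    for j, d in enumerate(schema):
        i = d.site - 1
        letter = window.residues[i]
        if d.family == FAMILY_CARBON:
            vec[j] = carbon[i]
            continue
        if letter == PAD:
            continue  # all non-carbon features are 0 at pads
        prof = profiles[i]
        if d.family == FAMILY_PSSM:
            vec[j] = prof.pssm_row[AA_ALPHABET.index(d.subname)]
        elif d.family == FAMILY_AAFACTOR:
            vec[j] = tables.aa_factors[letter][FACTOR_NAMES.index(d.subname)]
        elif d.family == FAMILY_DISORDER:
            vec[j] = prof.disorder
        elif d.family == FAMILY_SS:
            vec[j] = 1.0 if prof.ss_class == d.subname else 0.0
        elif d.family == FAMILY_ACC:
            vec[j] = 1.0 if prof.acc_class == d.subname else 0.0
        elif d.family == FAMILY_INTERFACE_SURFACE:
            table = (
                tables.interface_propensity
                if d.subname == "Interface"
                else tables.surface_propensity
            )
            vec[j] = table[letter]
        elif d.family == FAMILY_GAINLOSS:
            vec[j] = tables.gain_loss[letter]
    return vec


@dataclass
class FeatureMatrix:
    """Samples x features table with labels, column names and provenance."""

    values: np.ndarray
    labels: np.ndarray  # int8, 1 = positive, 0 = negative
    names: list[str]
    sample_ids: list[str]
    schema: FeatureSchema | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, m = self.values.shape
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise ValueError("labels/sample_ids length does not match rows")
        if len(self.names) != m:
            raise ValueError("names length does not match columns")
        if self.schema is not None and len(self.schema) != m:
            raise ValueError("schema length does not match columns")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def encode_dataset(
    windows: Sequence[PeptideWindow],
    profiles: Sequence[Sequence[ResidueProfile | None]],
    tables: PropertyTables,
    schema: FeatureSchema,
    standardize: bool = False,
) -> FeatureMatrix:
    """Encode a window set into a :class:`FeatureMatrix`.

    With ``standardize=True`` each column is z-scored (constant columns
    are left at zero after centering); raw values are the default.
    """
    if len(windows) != len(profiles):
        raise ValueError("one profile list per window required")
    values = np.empty((len(windows), len(schema)), dtype=float)
    for i, (w, p) in enumerate(zip(windows, profiles)):
        values[i] = encode(w, p, tables, schema)
    if standardize:
        mu = values.mean(axis=0)
        sd = values.std(axis=0)
        sd[sd == 0] = 1.0
        values = (values - mu) / sd
    labels = np.array([1 if w.label == POSITIVE else 0 for w in windows], dtype=np.int8)
    ids = [f"{w.protein_id}:{w.center_pos}" for w in windows]
    return FeatureMatrix(values, labels, schema.names, ids, schema)


# ---------------------------------------------------------------------------
# Serialization


def write_matrix_tsv(
    matrix: FeatureMatrix,
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Write the matrix as TSV plus a JSON metadata sidecar (``<path>.json``)."""
    df = pd.DataFrame(matrix.values, columns=matrix.names)
    df.insert(0, "sample_id", matrix.sample_ids)
    df.insert(1, "label", ["positive" if v else "negative" for v in matrix.labels])
    df.to_csv(path, sep="\t", index=False)
    meta = {
        "n_samples": matrix.n_samples,
        "n_features": matrix.n_features,
        "flank": matrix.schema.flank if matrix.schema else None,
        "carbon_deviation_sign": "residue_minus_window_mean",
    }
    if metadata:
        meta.update(metadata)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_matrix_tsv(path: str | Path) -> FeatureMatrix:
    """Read a matrix written by :func:`write_matrix_tsv`.

    The schema is reattached from the sidecar's flank when the column
    names match the canonical schema of that flank.
    """
    df = pd.read_csv(path, sep="\t")
    sample_ids = df["sample_id"].astype(str).tolist()
    labels = (df["label"] == "positive").astype(np.int8).to_numpy()
    values = df.drop(columns=["sample_id", "label"])
    schema = None
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        flank = meta.get("flank")
        if flank is not None:
            candidate = build_schema(int(flank))
            if candidate.names == list(values.columns):
                schema = candidate
    return FeatureMatrix(
        values.to_numpy(dtype=float),
        labels,
        list(values.columns),
        sample_ids,
        schema,
    )
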