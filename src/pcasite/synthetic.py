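"""Self-contained synthetic fixtures for every pipeline stage.

Two generation routes, both driven by the same :class:`SyntheticSpec`:

* the **window + profile route** emits protein sequences, site
  annotations and per-residue annotation tracks, exercising the
  dataset -> annotations -> encoder path end-to-end;
* the **direct matrix route** draws a feature matrix with planted
  informative columns, for fast feature-ranking and classifier tests.

Default study conditions mirror the real internal-pyroglutamate
dataset: 333 positive windows, a 1:5 positive:negative ratio and a
flank of 10 (21-residue windows, 1998 samples).  Informative columns
separate the class means by ``effect_size`` noise standard deviations;
one-hot families stay valid one-hots and are made informative through
class-dependent category probabilities instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import annotations as ann
from . import dataset as ds
from .encoder import (
    FAMILY_ACC,
    FAMILY_SS,
    FeatureMatrix,
    FeatureSchema,
    build_schema,
    encode_dataset,
)

#: Background amino-acid composition for synthetic sequences (uniform).
UNIFORM_COMPOSITION = {aa: 1.0 / 20.0 for aa in ds.AA_ALPHABET}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic study.

    ``effect_size`` is the class-mean separation of an informative
    continuous column in units of its noise standard deviation.
    """

    n_positive: int = 333
    neg_ratio: int = 5
    flank: int = 10
    informative_columns: tuple[int, ...] = ()
    effect_size: float = 0.0
    seed: int = 0
    n_features: int | None = None  # None -> full window schema
    composition: dict[str, float] = field(
        default_factory=lambda: dict(UNIFORM_COMPOSITION)
    )

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.neg_ratio < 1:
            raise ValueError("n_positive and neg_ratio must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.n_positive * (1 + self.neg_ratio)

    @property
    def window_length(self) -> int:
        return 2 * self.flank + 1


def _draw_window(rng: np.random.Generator, spec: SyntheticSpec) -> str:
    letters = list(spec.composition)
    probs = np.array([spec.composition[a] for a in letters], dtype=float)
    probs = probs / probs.sum()
    chars = rng.choice(letters, size=spec.window_length, p=probs)
    chars[spec.flank] = "Q"
    return "".join(chars)


def generate_windows(spec: SyntheticSpec) -> list[ds.PeptideWindow]:
    """Draw unique synthetic windows: positives first, then negatives.

    All windows are full length (no pads) with Q at the center;
    deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    windows: list[ds.PeptideWindow] = []
    labels = [ds.POSITIVE] * spec.n_positive + [ds.NEGATIVE] * (
        spec.n_positive * spec.neg_ratio
    )
    for i, label in enumerate(labels):
        frag = _draw_window(rng, spec)
        while frag in seen:
            frag = _draw_window(rng, spec)
        seen.add(frag)
        windows.append(
            ds.PeptideWindow(f"SYN{i:05d}", spec.flank + 1, frag, label)
        )
    return windows


def generate_sequences_and_sites(
    spec: SyntheticSpec,
    protein_length: int = 200,
) -> tuple[dict[str, str], list[ds.SiteAnnotation]]:
    """Emit raw inputs for the dataset stage: FASTA-ready sequences plus
    site annotations.

    One protein is generated per positive site, with the annotated Q at
    the protein center; the remaining residues are background draws, so
    each protein also carries unannotated internal Q sites that form the
    negative candidate pool.
    """
    rng = np.random.default_rng(spec.seed)
    letters = list(spec.composition)
    probs = np.array([spec.composition[a] for a in letters], dtype=float)
    probs = probs / probs.sum()
    center = protein_length // 2  # 0-based index of the annotated site
    sequences: dict[str, str] = {}
    sites: list[ds.SiteAnnotation] = []
    for i in range(spec.n_positive):
        pid = f"SYNPROT{i:05d}"
        chars = rng.choice(letters, size=protein_length, p=probs)
        chars[center] = "Q"
        sequences[pid] = "".join(chars)
        sites.append(ds.SiteAnnotation(pid, center + 1, "Q"))
    return sequences, sites


def generate_profiles(
    windows: Sequence[ds.PeptideWindow],
    spec: SyntheticSpec,
    bias: float = 0.0,
    informative_sites: Sequence[int] = (),
) -> list[list[ann.ResidueProfile | None]]:
    """Window+profile route: synthetic annotation tracks per window."""
    return ann.synthesize_profiles(
        windows, seed=spec.seed + 1, bias=bias, informative_sites=informative_sites
    )


def generate_encoded_dataset(
    spec: SyntheticSpec,
    bias: float = 0.0,
    informative_sites: Sequence[int] = (),
    tables: ann.PropertyTables | None = None,
) -> tuple[list[ds.PeptideWindow], FeatureMatrix]:
    """End-to-end window+profile route: windows -> profiles -> matrix."""
    schema = build_schema(spec.flank)
    windows = generate_windows(spec)
    profiles = generate_profiles(windows, spec, bias, informative_sites)
    tables = tables or ann.load_property_tables()
    return windows, encode_dataset(windows, profiles, tables, schema)


def generate_matrix(
    spec: SyntheticSpec,
    schema: FeatureSchema | None = None,
) -> FeatureMatrix:
    """Direct matrix route: planted-signal feature matrix.

    Without a schema, ``spec.n_features`` plain continuous columns are
    drawn (unit-variance Gaussian noise); columns listed in
    ``spec.informative_columns`` get their positive-class mean shifted
    by ``effect_size``.  With a schema, one-hot families (secondary
    structure, accessibility) are sampled as valid one-hots; a one-hot
    family containing an informative column becomes informative through
    class-dependent category probabilities.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    labels = np.zeros(n, dtype=np.int8)
    labels[: spec.n_positive] = 1
    informative = set(int(j) for j in spec.informative_columns)

    if schema is None:
        n_feat = spec.n_features if spec.n_features is not None else 200
        if informative and max(informative) >= n_feat:
            raise ValueError("informative column index out of range")
        values = rng.standard_normal((n, n_feat))
        for j in informative:
            values[labels == 1, j] += spec.effect_size
        names = [f"F{j:04d}" for j in range(n_feat)]
    else:
        n_feat = len(schema)
        if informative and max(informative) >= n_feat:
            raise ValueError("informative column index out of range for schema")
        values = np.zeros((n, n_feat))
        # category-probability tilt for informative one-hot families
        delta = min(0.3, 0.1 * spec.effect_size)
        j = 0
        while j < n_feat:
            d = schema[j]
            if d.family == FAMILY_SS:
                cols = [j, j + 1, j + 2]
                values[:, cols] = _one_hot_block(
                    rng, labels, 3, delta if informative & set(cols) else 0.0
                )
                j += 3
            elif d.family == FAMILY_ACC:
                cols = [j, j + 1]
                values[:, cols] = _one_hot_block(
                    rng, labels, 2, delta if informative & set(cols) else 0.0
                )
                j += 2
            else:
                values[:, j] = rng.standard_normal(n)
                if j in informative:
                    values[labels == 1, j] += spec.effect_size
                j += 1
        names = schema.names
    ids = [f"SYN{i:05d}" for i in range(n)]
    return FeatureMatrix(values, labels, names, ids, schema)


def _one_hot_block(
    rng: np.random.Generator,
    labels: np.ndarray,
    k: int,
    delta: float,
) -> np.ndarray:
    """Sample a valid one-hot block; positives favor category 0 by delta."""
    n = len(labels)
    base = np.full(k, 1.0 / k)
    tilted = base.copy()
    tilted[0] += delta
    tilted[1:] -= delta / (k - 1)
    out = np.zeros((n, k))
    for i in range(n):
        p = tilted if labels[i] else base
        out[i, rng.choice(k, p=p)] = 1.0
    return out


def write_fixture_files(
    spec: SyntheticSpec,
    out_dir: str | Path,
    protein_length: int = 200,
    bias: float = 0.0,
    informative_sites: Sequence[int] = (),
) -> dict[str, Path]:
    """Write a complete on-disk fixture: FASTA, sites TSV, per-protein
    PSSM files and disorder/SS/ACC tracks.

    Tracks cover every residue of every protein so any window extracted
    from the sequences can be encoded.  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sequences, sites = generate_sequences_and_sites(spec, protein_length)
    rng = np.random.default_rng(spec.seed + 2)
    annotated = {(s.protein_id, s.position) for s in sites}

    fasta = out / "proteins.fasta"
    with fasta.open("w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n{seq}\n")
    sites_path = out / "sites.tsv"
    with sites_path.open("w") as fh:
        fh.write("protein_id\tposition\tresidue\n")
        for s in sites:
            fh.write(f"{s.protein_id}\t{s.position}\t{s.residue}\n")

    pssm_dir = out / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    dis_rows, ss_rows, acc_rows = [], [], []
    informative = set(informative_sites)
    for pid, seq in sequences.items():
        scores = rng.integers(-5, 8, size=(len(seq), 20)).astype(float)
        if bias:
            for site in informative:
                # window site -> protein position around the annotated center
                for pos in [
                    p for (q, p) in annotated if q == pid
                ]:
                    tgt = pos - (spec.flank + 1) + site
                    if 1 <= tgt <= len(seq):
                        scores[tgt - 1] += round(bias)
        ann.write_pssm(ann.Pssm(seq, scores), pssm_dir / f"{pid}.pssm")
        for pos in range(1, len(seq) + 1):
            dis_rows.append((pid, pos, f"{rng.uniform(0, 1):.4f}"))
            ss_rows.append((pid, pos, rng.choice(ann.SS_CLASSES)))
            acc_rows.append((pid, pos, rng.choice(ann.ACC_CLASSES)))
    for name, rows in (
        ("disorder.tsv", dis_rows),
        ("ss.tsv", ss_rows),
        ("acc.tsv", acc_rows),
    ):
        with (out / name).open("w") as fh:
            fh.write("protein_id\tposition\tvalue\n")
            for pid, pos, val in rows:
                fh.write(f"{pid}\t{pos}\t{val}\n")
    return {
        "fasta": fasta,
        "sites": sites_path,
        "pssm_dir": pssm_dir,
        "disorder": out / "disorder.tsv",
        "ss": out / "ss.tsv",
        "acc": out / "acc.tsv",
    }
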