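"""Molecular descriptor computation and descriptor-table handling.

Descriptors are the independent variables of a QSRR model: numeric
properties computed from 2D molecular structure (counts, topological
indices, partition coefficients).  Everything here is strictly 2D — no
geometry optimisation or conformer generation is ever performed, so two
runs on the same SMILES are bitwise identical.

Two sources of descriptors are supported:

* :func:`compute_descriptors` — computed from SMILES with RDKit, under a
  name map that also exposes the CDK-style names common in the QSRR
  literature (``tpsaEfficiency``, ``nBase``, ``MDEC.33`` ...);
* :func:`load_descriptor_table` — a user-supplied delimited table of
  a-priori descriptors (e.g. pKa1, pKa2, logP from a prediction service).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as _RD
from rdkit.Chem import rdmolops

__all__ = [
    "SoluteRecord",
    "DescriptorMatrix",
    "CleaningReport",
    "compute_descriptors",
    "clean_matrix",
    "load_descriptor_table",
    "available_descriptors",
    "DescriptorError",
]


class DescriptorError(ValueError):
    """Raised for unparseable structures or unknown descriptor names."""


@dataclass
class SoluteRecord:
    """One analyte: identifier, optional structure and group label.

    ``smiles`` may be empty when descriptors come from a user-supplied
    table; ``group`` is a free categorical label (e.g. "sugars",
    "amino acids") used only for per-group modelling.
    """

    id: str
    name: str = ""
    smiles: str = ""
    group: str = ""

    def mol(self):
        """Parse the SMILES; raise :class:`DescriptorError` if invalid."""
        if not self.smiles:
            raise DescriptorError(f"solute {self.id!r} has no structure")
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise DescriptorError(
                f"solute {self.id!r}: unparseable SMILES {self.smiles!r}"
            )
        return m


@dataclass
class DescriptorMatrix:
    """Solutes x descriptors, with per-descriptor provenance.

    Thin wrapper around a float DataFrame (index = solute ids, columns =
    descriptor names, NaN = missing) carrying a provenance tag per column:
    ``"computed-2D"`` or ``"user-supplied"``.
    """

    frame: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            dups = self.frame.columns[self.frame.columns.duplicated()].tolist()
            raise ValueError(f"duplicate descriptor names: {dups}")
        if self.frame.index.duplicated().any():
            dups = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate solute ids: {dups}")
        self.frame = self.frame.astype(float)
        for c in self.frame.columns:
            self.provenance.setdefault(c, "computed-2D")

    @property
    def solute_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def subset(self, names: list[str]) -> "DescriptorMatrix":
        missing = [n for n in names if n not in self.frame.columns]
        if missing:
            raise KeyError(f"descriptor(s) not in matrix: {missing}")
        return DescriptorMatrix(
            self.frame[names].copy(),
            {n: self.provenance[n] for n in names},
        )


# ---------------------------------------------------------------------------
# CDK-style descriptors the QSRR literature names, implemented over RDKit.
# ---------------------------------------------------------------------------

_ACIDIC_SMARTS = [
    "[$([O;H1]-[C,S,P]=O)]",
    "[$([*;-;!$(*~[*;+])])]",
    "[$([NH](S(=O)(=O))C(F)(F)F)]",
    "[$(n1nnnc1)]",
]
_BASIC_SMARTS = [
    "[$([NH2]-[CX4])]",
    "[$([NH](-[CX4])-[CX4])]",
    "[$(N(-[CX4])(-[CX4])-[CX4])]",
    "[$([*;+;!$(*~[*;-])])]",
    "[$(N=C-N)]",
    "[$(N-C=N)]",
]

_acid_pats = [Chem.MolFromSmarts(s) for s in _ACIDIC_SMARTS]
_base_pats = [Chem.MolFromSmarts(s) for s in _BASIC_SMARTS]
_snh2_pat = Chem.MolFromSmarts("[NX3;H2;v3;!$([N]~[!#6])]")


def _smarts_count(mol, patterns) -> int:
    seen: set[int] = set()
    for p in patterns:
        for match in mol.GetSubstructMatches(p):
            seen.update(match)
    return len(seen)


def _tpsa_efficiency(mol) -> float:
    """Topological polar surface area scaled by molecular weight.

    Dimensionless-ish ratio in roughly [0, 1]; the fractional-PSA variant
    used under this name by CDK/rcdk descriptor sets.
    """
    mw = _RD.MolWt(mol)
    return _RD.TPSA(mol) / mw if mw > 0 else 0.0


def _c2sp3(mol) -> int:
    """Count of sp3 carbons bonded to exactly two other carbons."""
    n = 0
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6:
            continue
        if atom.GetHybridization() != Chem.HybridizationType.SP3:
            continue
        ncarbon = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 6)
        if ncarbon == 2:
            n += 1
    return n


def _mdec_33(mol) -> float:
    """Molecular distance-edge index between tertiary carbons.

    MDE(C;3,3) = n / d**2 with d the geometric mean of the topological
    distances over all pairs of carbons that are each bonded to exactly
    three other carbons; 0 when fewer than two such atoms exist.
    """
    tertiary = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6
        and sum(1 for nb in a.GetNeighbors() if nb.GetAtomicNum() == 6) == 3
    ]
    if len(tertiary) < 2:
        return 0.0
    dmat = rdmolops.GetDistanceMatrix(mol)
    log_prod = 0.0
    npairs = 0
    for i, ai in enumerate(tertiary):
        for aj in tertiary[i + 1 :]:
            log_prod += math.log(dmat[ai, aj])
            npairs += 1
    dbar = math.exp(log_prod / (2 * npairs))
    return npairs / (dbar * dbar)


#: Map from literature (CDK-style) descriptor names to implementations.
#: Values are callables mol -> number.  RDKit-native names (fr_C_O_noCOO,
#: MinPartialCharge, ...) resolve directly through Descriptors.descList and
#: need no entry here.  XLogP has no RDKit implementation and is mapped to
#: Crippen MolLogP, the nearest computed logP available.
CDK_NAME_MAP: dict[str, object] = {
    "tpsaEfficiency": _tpsa_efficiency,
    "XLogP": _RD.MolLogP,
    "nA": lambda m: _smarts_count(m, _acid_pats),
    "nB": lambda m: _smarts_count(m, _base_pats),
    "nBase": lambda m: _smarts_count(m, _base_pats),
    "nAcid": lambda m: _smarts_count(m, _acid_pats),
    "nR": _RD.RingCount,
    "nHBAcc": _RD.NumHAcceptors,
    "nHBDon": _RD.NumHDonors,
    "C2SP3": _c2sp3,
    "khs.sNH2": lambda m: len(m.GetSubstructMatches(_snh2_pat)),
    "MDEC.33": _mdec_33,
}

_RDKIT_2D: dict[str, object] = {name: fn for name, fn in _RD.descList}
# RDKit's registered descriptors are all 2D (no conformer dependence), in
# keeping with the no-geometry-optimisation policy; 3D descriptors live in
# rdkit.Chem.Descriptors3D and are deliberately not imported.


def available_descriptors() -> list[str]:
    """All descriptor names :func:`compute_descriptors` can resolve."""
    names = set(_RDKIT_2D) | set(CDK_NAME_MAP)
    return sorted(names)


def _resolve(name: str):
    if name in CDK_NAME_MAP:
        return CDK_NAME_MAP[name]
    if name in _RDKIT_2D:
        return _RDKIT_2D[name]
    raise DescriptorError(
        f"unknown descriptor {name!r}: not an RDKit 2D descriptor and not in "
        f"the CDK-style name map"
    )


def compute_descriptors(
    solutes: list[SoluteRecord],
    descriptor_set: list[str] | str = "all",
) -> DescriptorMatrix:
    """Compute 2D descriptors for every solute.

    Parameters
    ----------
    solutes
        Records with parseable SMILES.  Unparseable structures raise a
        single :class:`DescriptorError` listing every offending id.
    descriptor_set
        Explicit name list, or ``"all"`` for every resolvable 2D
        descriptor.  Unknown names raise rather than being dropped.

    Returns
    -------
    DescriptorMatrix with provenance ``"computed-2D"`` for all columns.
    Descriptors that fail on a particular molecule (e.g. charge models on
    exotic atoms) yield NaN there, left for :func:`clean_matrix`.
    """
    if isinstance(descriptor_set, str):
        if descriptor_set != "all":
            raise DescriptorError(
                f"descriptor_set must be a name list or 'all', got {descriptor_set!r}"
            )
        names = available_descriptors()
    else:
        names = list(descriptor_set)
    fns = {n: _resolve(n) for n in names}

    bad: list[str] = []
    mols = {}
    for s in solutes:
        try:
            mols[s.id] = s.mol()
        except DescriptorError:
            bad.append(s.id)
    if bad:
        raise DescriptorError(f"unparseable SMILES for solute id(s): {bad}")

    rows = {}
    for s in solutes:
        mol = mols[s.id]
        row = []
        for n in names:
            try:
                v = float(fns[n](mol))
            except Exception:
                v = float("nan")
            row.append(v)
        rows[s.id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    frame.index.name = "id"
    return DescriptorMatrix(frame, {n: "computed-2D" for n in names})


@dataclass
class CleaningReport:
    """Which columns :func:`clean_matrix` removed, and why."""

    removed: list[tuple[str, str]] = field(default_factory=list)

    def removed_names(self) -> list[str]:
        return [n for n, _ in self.removed]


def clean_matrix(
    dm: DescriptorMatrix,
    drop_missing: bool = True,
    impute: str | None = None,
) -> tuple[DescriptorMatrix, CleaningReport]:
    """Drop unusable descriptor columns before model building.

    Zero-variance columns are always removed (they carry no information
    and break least squares alongside an intercept).  Columns containing
    missing values are removed under the default policy — this keeps the
    solute count fixed — or imputed with the column mean/median when
    ``impute`` is ``"mean"``/``"median"`` and ``drop_missing`` is False.
    """
    if dm.frame.empty:
        raise ValueError("empty descriptor matrix")
    frame = dm.frame.copy()
    report = CleaningReport()

    if not drop_missing and impute:
        if impute not in ("mean", "median"):
            raise ValueError(f"unknown imputation policy {impute!r}")
        fill = frame.mean() if impute == "mean" else frame.median()
        frame = frame.fillna(fill)

    for col in list(frame.columns):
        colvals = frame[col]
        if colvals.isna().any():
            frame = frame.drop(columns=[col])
            report.removed.append((col, "missing values"))
        elif colvals.nunique(dropna=False) <= 1:
            frame = frame.drop(columns=[col])
            report.removed.append((col, "zero variance"))
    if frame.shape[1] == 0:
        raise ValueError("no usable descriptors after cleaning")
    prov = {c: dm.provenance[c] for c in frame.columns}
    return DescriptorMatrix(frame, prov), report


def load_descriptor_table(path, id_column: str = "id") -> DescriptorMatrix:
    """Load a user-supplied descriptor table from delimited text.

    Comma or tab delimiter is autodetected from the header line.  Every
    column other than the id becomes a descriptor with provenance
    ``"user-supplied"``; cells that do not parse as numbers become NaN.
    """
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if id_column not in raw.columns:
        raise ValueError(f"id column {id_column!r} not found in {path}")
    ids = raw[id_column].astype(str)
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].tolist()
        raise ValueError(f"duplicate ids in descriptor table: {dups}")
    body = raw.drop(columns=[id_column]).apply(pd.to_numeric, errors="coerce")
    body.index = pd.Index(ids, name="id")
    return DescriptorMatrix(body, {c: "user-supplied" for c in body.columns})
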