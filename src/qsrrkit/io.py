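"""Reading and writing the delimited-text formats of the toolkit.

The solute table is one delimited file (comma or tab, autodetected) with
a header row and columns::

    id [, name] [, smiles] [, group] , tR_<label> [, tR_<label> ...]

Retention columns are auto-discovered by the ``tR_`` prefix (overridable);
blank retention cells mean "not measured on that column" and the solute is
kept.  Structures may alternatively come from an SDF file whose records
carry the solute id as a property.
"""

from __future__ import annotations

import pandas as pd
from rdkit import Chem

from .descriptors import SoluteRecord
from .model import RetentionTable

__all__ = ["read_solute_table", "write_solute_table", "attach_sdf_structures"]

RT_PREFIX = "tR_"


def read_solute_table(
    path, rt_prefix: str = RT_PREFIX
) -> tuple[list[SoluteRecord], RetentionTable]:
    """Parse a solute CSV/TSV into records plus a retention table."""
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if "id" not in raw.columns:
        raise ValueError(f"{path}: missing required 'id' column")
    ids = raw["id"].astype(str)
    if ids.duplicated().any():
        raise ValueError(
            f"{path}: duplicate solute id(s): {ids[ids.duplicated()].tolist()}"
        )
    rt_cols = [c for c in raw.columns if c.startswith(rt_prefix)]
    if not rt_cols:
        raise ValueError(
            f"{path}: no retention columns (prefix {rt_prefix!r}) found"
        )
    solutes = [
        SoluteRecord(
            id=str(row["id"]),
            name=str(row.get("name", "") or ""),
            smiles=str(row.get("smiles", "") or ""),
            group=str(row.get("group", "") or ""),
        )
        for row in raw.fillna("").to_dict("records")
    ]
    rt_frame = raw[rt_cols].apply(pd.to_numeric, errors="coerce")
    rt_frame.index = pd.Index(ids, name="id")
    return solutes, RetentionTable(rt_frame)


def write_solute_table(
    path,
    solutes: list[SoluteRecord],
    retention: RetentionTable,
    descriptors=None,
) -> None:
    """Write solutes (+ optional descriptor columns) in the readable dialect."""
    base = pd.DataFrame(
        {
            "id": [s.id for s in solutes],
            "name": [s.name for s in solutes],
            "smiles": [s.smiles for s in solutes],
            "group": [s.group for s in solutes],
        }
    ).set_index("id")
    frames = [base]
    if descriptors is not None:
        frames.append(descriptors.frame)
    frames.append(retention.frame)
    pd.concat(frames, axis=1).to_csv(path)


def attach_sdf_structures(
    solutes: list[SoluteRecord], sdf_path, id_property: str = "id"
) -> list[SoluteRecord]:
    """Fill in SMILES from an SDF file keyed by an id property.

    Records whose id matches a solute overwrite that solute's SMILES with
    the canonical SMILES of the SDF structure; solutes without a matching
    record are left untouched.
    """
    by_id = {s.id: s for s in solutes}
    supplier = Chem.SDMolSupplier(str(sdf_path))
    for mol in supplier:
        if mol is None:
            continue
        if mol.HasProp(id_property):
            key = mol.GetProp(id_property)
        elif mol.HasProp("_Name"):
            key = mol.GetProp("_Name")
        else:
            continue
        if key in by_id:
            by_id[key].smiles = Chem.MolToSmiles(mol)
    return solutes
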