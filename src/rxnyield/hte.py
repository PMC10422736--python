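"""High-throughput experimentation (HTE) data reduction.

Plate-scale C-N coupling screens quantify each reaction by UPLC-UV against
an internal standard (IS) added at a fixed mole ratio c to the theoretical
product amount. The yield proxy is

    ratio_UV = (A_product * c) / A_IS * 100%

with A_product and A_IS the 254 nm response areas and c = 0.0625
equivalents by default. Internally ratios are kept as fractions in [0, 1];
the percent form is an I/O convention. Values above 1 are retained with a
warning rather than clipped.

Reactions are grouped by the aromatic class of the ring bearing the
reactive group of each substrate: benzenoid (Ph) vs pyridyl (Py), giving
the four quadrants G1 = Ph-NH2 x Ph-Br, G2 = Ph-NH2 x Py-Br,
G3 = Py-NH2 x Ph-Br, G4 = Py-NH2 x Py-Br.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

DEFAULT_IS_EQUIV = 0.0625  # internal-standard mole ratio (equivalents)

GROUPS = ("G1", "G2", "G3", "G4")


class UnclassifiableSubstrateError(ValueError):
    """Raised when a substrate carries no recognizable reactive group."""


def compute_ratio_uv(
    a_product: float, a_is: float, c: float = DEFAULT_IS_EQUIV, percent: bool = True
) -> float:
    """UV response ratio of product over internal standard.

    Returns a percentage by default; ``percent=False`` gives the fraction.
    """
    if a_is <= 0:
        raise ValueError(f"invalid internal-standard signal A_IS={a_is} (must be > 0)")
    if a_product < 0:
        raise ValueError(f"negative product signal A_product={a_product}")
    if c <= 0:
        raise ValueError(f"mole-ratio constant c={c} must be > 0")
    frac = (a_product * c) / a_is
    if frac > 1.0:
        warnings.warn(
            f"ratio_UV {frac:.3f} exceeds 1 (100%); retained unclipped",
            stacklevel=2,
        )
    return frac * 100.0 if percent else frac


def _ring_class(mol: Chem.Mol, query: Chem.Mol) -> str | None:
    """'Ph' or 'Py' for the ring directly bearing the matched reactive group.

    Fused or multi-ring systems classify by that ring alone: pyridyl if the
    six-membered aromatic ring holding the reactive carbon/nitrogen contains
    a ring nitrogen, benzenoid if it is all-carbon.
    """
    matches = mol.GetSubstructMatches(query)
    ring_info = mol.GetRingInfo()
    for match in matches:
        ring_atom = match[0]  # first query atom is the aromatic ring atom
        for ring in ring_info.AtomRings():
            if ring_atom in ring and len(ring) == 6:
                symbols = {mol.GetAtomWithIdx(i).GetSymbol() for i in ring}
                if not all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
                    continue
                return "Py" if "N" in symbols else "Ph"
    return None


_AMINE_QUERY = Chem.MolFromSmarts("[c;$(c-[NH2])]")
_BROMIDE_QUERY = Chem.MolFromSmarts("[c;$(c-Br)]")


def classify_amine(smiles: str) -> str:
    """'Ph' or 'Py' by the aromatic ring bearing the primary amine."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise UnclassifiableSubstrateError(f"unparseable amine SMILES: {smiles!r}")
    cls = _ring_class(mol, _AMINE_QUERY)
    if cls is None:
        raise UnclassifiableSubstrateError(
            f"no aryl primary amine found in {smiles!r}"
        )
    return cls


def classify_bromide(smiles: str) -> str:
    """'Ph' or 'Py' by the aromatic ring bearing the bromide."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise UnclassifiableSubstrateError(f"unparseable bromide SMILES: {smiles!r}")
    cls = _ring_class(mol, _BROMIDE_QUERY)
    if cls is None:
        raise UnclassifiableSubstrateError(f"no aryl bromide found in {smiles!r}")
    return cls


def assign_group(amine_smiles: str, bromide_smiles: str) -> str:
    """Quadrant label G1-G4 from the substrate aromatic classes."""
    amine = classify_amine(amine_smiles)
    bromide = classify_bromide(bromide_smiles)
    return {
        ("Ph", "Ph"): "G1",
        ("Ph", "Py"): "G2",
        ("Py", "Ph"): "G3",
        ("Py", "Py"): "G4",
    }[(amine, bromide)]


@dataclass
class GroupSummary:
    group: str
    count: int
    n_at_or_above: int
    fraction_at_or_above: float | None  # None when the group is empty


def summarize_groups(
    df: pd.DataFrame,
    ratio_column: str = "ratio_uv",
    group_column: str = "group",
    threshold: float = 0.5,
) -> dict[str, GroupSummary]:
    """Per-group counts and the fraction of reactions with ratio >= threshold."""
    out: dict[str, GroupSummary] = {}
    for g in GROUPS:
        sub = df[df[group_column] == g]
        n = len(sub)
        hits = int((sub[ratio_column] >= threshold).sum()) if n else 0
        out[g] = GroupSummary(
            group=g,
            count=n,
            n_at_or_above=hits,
            fraction_at_or_above=(hits / n if n else None),
        )
    return out


def heatmap_matrix(
    df: pd.DataFrame,
    amine_column: str = "amine_smiles",
    bromide_column: str = "bromide_smiles",
    ratio_column: str = "ratio_uv",
) -> pd.DataFrame:
    """Amine x bromide ratio matrix; absent combinations are NaN (failed or
    discarded reactions). Columns are amine ids prefixed 'A', rows bromide
    ids prefixed 'B', in first-appearance order."""
    amines = list(dict.fromkeys(df[amine_column]))
    bromides = list(dict.fromkeys(df[bromide_column]))
    mat = pd.DataFrame(
        np.nan,
        index=[f"B{i + 1}" for i in range(len(bromides))],
        columns=[f"A{i + 1}" for i in range(len(amines))],
    )
    a_pos = {s: i for i, s in enumerate(amines)}
    b_pos = {s: i for i, s in enumerate(bromides)}
    for _, row in df.iterrows():
        mat.iloc[b_pos[row[bromide_column]], a_pos[row[amine_column]]] = row[
            ratio_column
        ]
    return mat


def reduce_plate_table(
    df: pd.DataFrame,
    c: float = DEFAULT_IS_EQUIV,
    amine_column: str = "amine_smiles",
    bromide_column: str = "bromide_smiles",
) -> pd.DataFrame:
    """Full reduction of a plate table: compute ratio_uv (as a fraction in
    [0,1]) from A_product/A_IS columns when not already present, and assign
    the G1-G4 group per row."""
    out = df.copy()
    if "ratio_uv" not in out.columns:
        if not {"A_product", "A_IS"}.issubset(out.columns):
            raise KeyError(
                "need either a 'ratio_uv' column or 'A_product' and 'A_IS'"
            )
        out["ratio_uv"] = [
            compute_ratio_uv(p, s, c, percent=False)
            for p, s in zip(out["A_product"], out["A_IS"])
        ]
    out["group"] = [
        assign_group(a, b) for a, b in zip(out[amine_column], out[bromide_column])
    ]
    return out
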