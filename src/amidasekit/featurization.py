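"""Enzyme and substrate featurization for specificity modelling.

Enzyme features come from the multiple sequence alignment of active
amidase-signature (AS) enzymes, trimmed to the ~160-column signature
region and encoded column-wise with the first four published amino-acid
factor-analysis scores (Atchley factors): polarity (f1), secondary
structure (f2), molecular size (f3) and codon diversity (f4).

Substrate features combine generic descriptors (element counts, formal
charge count, functional-group counts) with engineered hydrolysis-aware
masses obtained by conceptually cutting the amide bond into three parts:

* ``MW_bond`` — the amide tail mass: the acyl substituent R on the
  carbonyl carbon, uncapped;
* ``MW_ring`` — the aryl mass: the N-aryl part with all its ring
  substituents;
* the connecting ``C(=O)NH`` unit (43.03 Da), so that for a standard
  secondary anilide ``MW_bond + MW_ring + 43.03 = MW``.

Non-anilide substrates carry special-case annotations that override the
fragmentation: ``acesulfame_rule`` (MW_ring and MW_bond are each half of
the molecule mass), ``primary_amide_rule`` (the nitrogen substituent is a
lone hydrogen, so MW_bond is one hydrogen mass and the carbonyl-side
fragment plays the ring role), ``ester_as_amide`` (aryl esters fragmented
at the ester as if it were an amide) and ``treat_as_anilide`` (amides
whose aryl sits on the carbonyl side; the aromatic fragment is assigned
to MW_ring and the ANILIDE indicator is forced on).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .hitcalling import ActivityMatrix

GAP = "-"

# First four amino-acid factor-analysis scores (polarity, secondary
# structure, molecular size, codon diversity).
ATCHLEY_FACTORS: dict[str, tuple[float, float, float, float]] = {
    "A": (-0.591, -1.302, -0.733, 1.570),
    "C": (-1.343, 0.465, -0.862, -1.020),
    "D": (1.050, 0.302, -3.656, -0.259),
    "E": (1.357, -1.453, 1.477, 0.113),
    "F": (-1.006, -0.590, 1.891, -0.397),
    "G": (-0.384, 1.652, 1.330, 1.045),
    "H": (0.336, -0.417, -1.673, -1.474),
    "I": (-1.239, -0.547, 2.131, 0.393),
    "K": (1.831, -0.561, 0.533, -0.277),
    "L": (-1.019, -0.987, -1.505, 1.266),
    "M": (-0.663, -1.524, 2.219, -1.005),
    "N": (0.945, 0.828, 1.299, -0.169),
    "P": (0.189, 2.081, -1.628, 0.421),
    "Q": (0.931, -0.179, -3.005, -0.503),
    "R": (1.538, -0.055, 1.502, 0.440),
    "S": (-0.228, 1.399, -4.760, 0.670),
    "T": (-0.032, 0.326, 2.213, 0.908),
    "V": (-1.337, -0.279, -0.544, 1.242),
    "W": (-0.595, 0.009, 0.672, -2.128),
    "Y": (0.260, 0.830, 3.097, -0.838),
}

#: Mass of the connecting C(=O)NH unit of a secondary amide, Da.
AMIDE_UNIT_MASS = 43.025

SPECIAL_CASES = (
    "standard_anilide",
    "acesulfame_rule",
    "primary_amide_rule",
    "ester_as_amide",
    "treat_as_anilide",
)

# Fixed, versioned functional-group vocabulary (SMARTS).
FUNCTIONAL_GROUP_SMARTS: dict[str, str] = {
    "amide": "[NX3][CX3](=O)",
    "ester": "[#6][CX3](=O)[OX2][#6]",
    "nitro": "[NX3+](=O)[O-]",
    "hydroxyl": "[OX2H]",
    "primary_amine": "[NX3;H2;!$([NX3][CX3]=[OX1])]",
    "halogen": "[F,Cl,Br,I]",
    "sulfonamide": "[SX4](=O)(=O)[NX3]",
}

ANILIDE_SMARTS = "[cX3][NX3][CX3]=[OX1]"

ELEMENTS = ("C", "H", "N", "O", "S", "F", "Cl", "Br", "I", "P")


class FeaturizationError(ValueError):
    """Raised on contract violations while building features."""


# ---------------------------------------------------------------------------
# Alignment handling
# ---------------------------------------------------------------------------

@dataclass
class TrimmedAlignment:
    """A signature-region alignment block plus its column provenance.

    ``column_map[i]`` gives the 0-based column of the original alignment
    behind trimmed column ``i``; feature names report 1-based original
    numbering so that modelled positions can be read off the published
    alignment coordinates.
    """

    sequences: dict[str, str]
    column_map: list[int]

    @property
    def n_columns(self) -> int:
        return len(self.column_map)


def _conserved_columns(sequences: dict[str, str]) -> dict[int, str]:
    rows = list(sequences.values())
    ncol = len(rows[0])
    out = {}
    for j in range(ncol):
        col = {row[j] for row in rows}
        if len(col) == 1:
            out[j] = rows[0][j]
    return out


def detect_triad(sequences: dict[str, str], motif_min_run: int = 5) -> tuple[int, int, int]:
    """Locate the conserved catalytic K..S..S triad columns.

    The AS family places the catalytic lysine before the Gly/Ser-rich
    motif and the two catalytic serines after it.  The detector finds
    fully conserved columns, the longest conserved Gly/Ser run of at
    least ``motif_min_run`` columns, and then the conserved K nearest
    before the run and the first two conserved S after it.  Raises when
    the layout cannot be identified unambiguously.
    """
    conserved = _conserved_columns(sequences)
    ncol = len(next(iter(sequences.values())))
    runs = []
    j = 0
    while j < ncol:
        if conserved.get(j) in ("G", "S"):
            start = j
            while j < ncol and conserved.get(j) in ("G", "S"):
                j += 1
            if j - start >= motif_min_run:
                runs.append((start, j))
        else:
            j += 1
    if len(runs) != 1:
        raise FeaturizationError(
            f"could not locate a unique Gly/Ser-rich motif run (found {len(runs)}); "
            "pass an explicit signature span"
        )
    m0, m1 = runs[0]
    ks = [c for c, r in conserved.items() if r == "K" and c < m0]
    ss = sorted(c for c, r in conserved.items() if r == "S" and c >= m1)
    if not ks or len(ss) < 2:
        raise FeaturizationError(
            "catalytic triad columns not found around the Gly/Ser motif; "
            "pass an explicit signature span"
        )
    return (ss[0], ss[1], max(ks))


def trim_to_signature(
    sequences: dict[str, str],
    span: tuple[int, int] | None = None,
    signature_length: int = 160,
) -> TrimmedAlignment:
    """Trim an alignment to the amidase-signature region.

    With an explicit ``span`` (half-open, 0-based) the block is cut
    directly.  Otherwise the catalytic triad is detected and a window of
    ``signature_length`` columns centred on the triad (clipped to the
    alignment and required to contain all three triad columns) is used.
    """
    ncol = len(next(iter(sequences.values())))
    if any(len(s) != ncol for s in sequences.values()):
        raise FeaturizationError("alignment rows differ in column count")
    if span is None:
        s1, s2, k = detect_triad(sequences)
        centre = (s1 + s2 + k) // 3
        start = max(0, min(centre - signature_length // 2, ncol - signature_length))
        span = (start, start + signature_length)
        if not (span[0] <= min(k, s1, s2) and max(k, s1, s2) < span[1]):
            raise FeaturizationError(
                "detected triad does not fit inside a signature-length window; "
                "pass an explicit span"
            )
    lo, hi = span
    if lo < 0 or hi > ncol or hi <= lo:
        raise FeaturizationError(f"signature span {span} exceeds alignment of {ncol} columns")
    block = {sid: seq[lo:hi] for sid, seq in sequences.items()}
    return TrimmedAlignment(sequences=block, column_map=list(range(lo, hi)))


def atchley_encode_alignment(
    block: TrimmedAlignment,
    gap_vector: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0),
) -> pd.DataFrame:
    """Encode each alignment column as four factor features per enzyme.

    Features are named ``AA<orig-column>_f<1..4>`` with the 1-based
    original alignment column, so importances can be reported in
    alignment coordinates.  Gaps map to ``gap_vector``.
    """
    if not block.sequences:
        raise FeaturizationError("empty alignment block")
    names = [f"AA{c + 1}_f{k}" for c in block.column_map for k in (1, 2, 3, 4)]
    rows = {}
    for sid, seq in block.sequences.items():
        vec = np.empty(len(names))
        for i, residue in enumerate(seq):
            if residue == GAP:
                vec[4 * i : 4 * i + 4] = gap_vector
            else:
                try:
                    vec[4 * i : 4 * i + 4] = ATCHLEY_FACTORS[residue]
                except KeyError:
                    raise FeaturizationError(
                        f"unknown residue {residue!r} in sequence {sid!r} at trimmed column {i}"
                    ) from None
        rows[sid] = vec
    return pd.DataFrame.from_dict(rows, orient="index", columns=names)


# ---------------------------------------------------------------------------
# Chemical descriptors
# ---------------------------------------------------------------------------

@dataclass
class ChemicalFeatures:
    """Descriptor vector for one substrate."""

    values: dict[str, float]
    special_case: str

    def as_series(self, name=None) -> pd.Series:
        return pd.Series(self.values, name=name)


def _fragment_mass(mol: Chem.Mol, start_idx: int, blocked: set[int]) -> float:
    """Mass of the connected fragment grown from ``start_idx`` without
    crossing ``blocked`` atoms, including implicit hydrogens."""
    pt = Chem.GetPeriodicTable()
    seen = {start_idx}
    stack = [start_idx]
    mass = 0.0
    while stack:
        idx = stack.pop()
        atom = mol.GetAtomWithIdx(idx)
        mass += pt.GetAtomicWeight(atom.GetAtomicNum()) + 1.008 * atom.GetTotalNumHs()
        for nb in atom.GetNeighbors():
            if nb.GetIdx() not in seen and nb.GetIdx() not in blocked:
                seen.add(nb.GetIdx())
                stack.append(nb.GetIdx())
    return mass


def _pick_hydrolyzable_bond(mol: Chem.Mol, as_ester: bool) -> tuple[int, int, int]:
    """Return (carbonyl C, carbonyl O, heteroatom) of the bond to cut.

    For amides, bonds whose nitrogen carries an aromatic substituent are
    preferred (the N-aryl amide of an anilide); for esters the aryl-O
    ester is matched.  Ambiguity beyond that is resolved by the lowest
    atom index for determinism.
    """
    if as_ester:
        patt = Chem.MolFromSmarts("[CX3](=[OX1])[OX2][c]")
    else:
        patt = Chem.MolFromSmarts("[CX3](=[OX1])[NX3]")
    matches = mol.GetSubstructMatches(patt)
    if not matches:
        raise FeaturizationError(
            "no hydrolyzable bond found; annotate the substrate with a special case"
        )
    def n_is_aryl(match):
        het = mol.GetAtomWithIdx(match[2])
        return any(nb.GetIsAromatic() for nb in het.GetNeighbors() if nb.GetIdx() != match[0])
    aryl = [m for m in matches if n_is_aryl(m)]
    chosen = sorted(aryl or matches)[0]
    return chosen[0], chosen[1], chosen[2]


def chemical_descriptors(smiles: str, special_case: str = "standard_anilide") -> ChemicalFeatures:
    """Compute the substrate descriptor vector from a SMILES string.

    Includes element counts (``n_<element>``), ``formal_charge_count``
    (atoms with nonzero formal charge), functional-group counts
    (``fg_<group>``), ``n_aromatic_rings``, the ``ANILIDE`` indicator,
    and the engineered masses ``MW``, ``MW_bond`` and ``MW_ring`` under
    the fragmentation rules described in the module docstring.
    """
    if special_case not in SPECIAL_CASES:
        raise FeaturizationError(f"unknown special case {special_case!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable structure: {smiles!r}")
    values: dict[str, float] = {}
    counts = {el: 0 for el in ELEMENTS}
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym in counts:
            counts[sym] += 1
        counts["H"] += atom.GetTotalNumHs()
    for el in ELEMENTS:
        values[f"n_{el}"] = float(counts[el])
    values["formal_charge_count"] = float(
        sum(1 for a in mol.GetAtoms() if a.GetFormalCharge() != 0)
    )
    for name, smarts in FUNCTIONAL_GROUP_SMARTS.items():
        values[f"fg_{name}"] = float(len(mol.GetSubstructMatches(Chem.MolFromSmarts(smarts))))
    values["n_aromatic_rings"] = float(Chem.rdMolDescriptors.CalcNumAromaticRings(mol))
    anilide = bool(mol.GetSubstructMatches(Chem.MolFromSmarts(ANILIDE_SMARTS)))
    if special_case == "treat_as_anilide":
        anilide = True
    values["ANILIDE"] = float(anilide)
    mw = float(Descriptors.MolWt(mol))
    values["MW"] = mw

    if special_case == "acesulfame_rule":
        values["MW_bond"] = mw / 2.0
        values["MW_ring"] = mw / 2.0
    else:
        as_ester = special_case == "ester_as_amide"
        c_idx, o_idx, het_idx = _pick_hydrolyzable_bond(mol, as_ester)
        carbonyl = mol.GetAtomWithIdx(c_idx)
        het = mol.GetAtomWithIdx(het_idx)
        acyl_neighbors = [
            nb.GetIdx() for nb in carbonyl.GetNeighbors() if nb.GetIdx() not in (o_idx, het_idx)
        ]
        het_neighbors = [nb.GetIdx() for nb in het.GetNeighbors() if nb.GetIdx() != c_idx]
        blocked = {c_idx, o_idx, het_idx}
        if acyl_neighbors:
            acyl_mass = _fragment_mass(mol, acyl_neighbors[0], blocked)
        else:
            acyl_mass = 1.008  # formyl: R is a lone hydrogen
        if het_neighbors:
            het_mass = sum(_fragment_mass(mol, idx, blocked) for idx in het_neighbors)
        else:
            het_mass = 1.008
        if special_case == "primary_amide_rule":
            # Primary amide: the nitrogen substituent is one hydrogen and
            # the carbonyl-side fragment carries the aryl role.
            values["MW_bond"] = 1.008
            values["MW_ring"] = acyl_mass
        elif special_case == "treat_as_anilide":
            # Aryl on the carbonyl side: the aromatic fragment is the ring.
            if _contains_aromatic(mol, acyl_neighbors, blocked):
                values["MW_bond"], values["MW_ring"] = het_mass, acyl_mass
            else:
                values["MW_bond"], values["MW_ring"] = acyl_mass, het_mass
        else:
            values["MW_bond"] = acyl_mass
            values["MW_ring"] = het_mass
    return ChemicalFeatures(values=values, special_case=special_case)


def _contains_aromatic(mol: Chem.Mol, start_indices: list[int], blocked: set[int]) -> bool:
    seen = set(start_indices)
    stack = list(start_indices)
    while stack:
        idx = stack.pop()
        if mol.GetAtomWithIdx(idx).GetIsAromatic():
            return True
        for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
            if nb.GetIdx() not in seen and nb.GetIdx() not in blocked:
                seen.add(nb.GetIdx())
                stack.append(nb.GetIdx())
    return False


def chemical_feature_table(substrates: pd.DataFrame) -> pd.DataFrame:
    """Descriptor table for a substrate panel.

    ``substrates`` needs columns ``substrate_id``, ``smiles`` and
    ``special_case``; returns one row per substrate indexed by id.
    """
    rows = {}
    for rec in substrates.itertuples():
        feats = chemical_descriptors(rec.smiles, rec.special_case)
        rows[rec.substrate_id] = feats.values
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Feature table assembly
# ---------------------------------------------------------------------------

@dataclass
class VarianceFilterConfig:
    """Low-variance feature screening.

    Zero-variance columns are always removed.  When ``near_zero`` is on,
    a column is additionally removed if the ratio of its most common to
    second most common value exceeds ``freq_ratio`` *and* the percentage
    of unique values is below ``unique_percent`` (the common screening
    convention for near-zero-variance predictors).
    """

    near_zero: bool = False
    freq_ratio: float = 95.0 / 5.0
    unique_percent: float = 10.0


@dataclass
class FeatureTable:
    """One row per enzyme-substrate pair with features, labels, provenance."""

    data: pd.DataFrame  # index: (enzyme_id, substrate_id); columns: features
    labels: pd.Series
    removed_features: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out["label"] = self.labels
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label=["enzyme_id", "substrate_id"])

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, index_col=[0, 1])
        labels = df.pop("label")
        return cls(data=df, labels=labels)


def _near_zero_variance(col: pd.Series, cfg: VarianceFilterConfig) -> bool:
    counts = col.value_counts()
    if len(counts) == 1:
        return True
    ratio = counts.iloc[0] / counts.iloc[1]
    unique_pct = 100.0 * len(counts) / len(col)
    return bool(cfg.near_zero and ratio > cfg.freq_ratio and unique_pct < cfg.unique_percent)


def build_feature_table(
    enzyme_features: pd.DataFrame,
    chemical_features: pd.DataFrame,
    activity: ActivityMatrix,
    variance_filter: VarianceFilterConfig | None = None,
) -> FeatureTable:
    """Cross-join enzyme and substrate features and attach labels.

    Rows are all pairs of the activity matrix; a missing label for any
    pair is an error.  Columns failing the variance screen are removed
    and recorded; filtering never removes rows.
    """
    variance_filter = variance_filter or VarianceFilterConfig()
    enzymes = [e for e in activity.enzyme_ids]
    substrates = [s for s in activity.substrate_ids]
    missing_e = [e for e in enzymes if e not in enzyme_features.index]
    missing_s = [s for s in substrates if s not in chemical_features.index]
    if missing_e or missing_s:
        raise FeaturizationError(
            f"features missing for enzymes {missing_e} / substrates {missing_s}"
        )
    index = pd.MultiIndex.from_product([enzymes, substrates], names=["enzyme_id", "substrate_id"])
    enz = enzyme_features.loc[index.get_level_values(0)].reset_index(drop=True)
    chem = chemical_features.loc[index.get_level_values(1)].reset_index(drop=True)
    data = pd.concat([enz, chem], axis=1)
    data.index = index
    if data.columns.duplicated().any():
        dupes = list(data.columns[data.columns.duplicated()])
        raise FeaturizationError(f"duplicate feature names: {dupes}")
    if data.isna().any().any():
        raise FeaturizationError("feature table contains missing values")
    labels = pd.Series(
        [activity.values.at[e, s] for e, s in index], index=index, name="label", dtype=int
    )
    removed = [c for c in data.columns if _near_zero_variance(data[c], variance_filter)]
    provenance = {
        c: ("enzyme_alignment" if c.startswith("AA") else "chemical_descriptor")
        for c in data.columns
    }
    return FeatureTable(
        data=data.drop(columns=removed),
        labels=labels,
        removed_features=removed,
        provenance={c: provenance[c] for c in data.columns if c not in removed},
    )
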