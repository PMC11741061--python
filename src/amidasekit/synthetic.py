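"""Synthetic screen generator: alignments, substrate panels, planted
activity and noisy assay readouts.

The generator emulates the statistical structure of a urine-derived
amidase-signature (AS) enzyme screen so the whole pipeline is testable
without external data:

* an AS-family protein alignment with a conserved catalytic triad
  (two serines and a lysine), a conserved Gly/Ser-rich motif, variable
  surface columns, and a handful of planted columns whose residue
  identity feeds the activity model;
* a substrate panel of anilides, aryl esters and primary amides drawn
  from a curated template list spanning amide-tail masses and formal
  charge states (random molecular graphs are never generated, so every
  structure parses and carries a known special-case class);
* a planted logistic activity rule over standardized chemical
  descriptors (amide-tail mass, molecule mass, formal-charge count) and
  Atchley-factor values at the planted alignment columns;
* noisy HPLC peak areas (multiplicative lognormal) and plate-reader OD
  time series (additive Gaussian) including replicates of the
  catalytically dead control enzyme and complete-turnover references.

Determinism: every operation derives its random stream from
``(cfg.seed, stage offset)``, so identical configurations reproduce
byte-identical outputs at every stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .featurization import ATCHLEY_FACTORS, chemical_descriptors
from .hitcalling import COLORIMETRIC, HPLC, MEASUREMENT_COLUMNS, HitCallingConfig

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# Conserved background columns avoid K and S so the catalytic triad and
# Gly/Ser motif remain the only conserved landmarks of those letters the
# trimming heuristic has to find.
BACKGROUND_ALPHABET = [a for a in AMINO_ACIDS if a not in "KS"]

CONTROL_ENZYME_ID = "CTRL-S146A"
REFERENCE_ID = "REF-100pct"

_STAGE_ENZYMES = 1
_STAGE_SUBSTRATES = 2
_STAGE_ACTIVITY = 3
_STAGE_MEASUREMENTS = 4

PLATE_TIME_GRID = [0.0, 50.0, 100.0, 300.0, 600.0, 900.0, 1250.0, 1800.0, 2600.0]

#: Curated substrate templates: (name, SMILES, assay route, special case,
#: evaluation time in minutes for colorimetric substrates).
CURATED_SUBSTRATES: list[tuple[str, str, str, str, float | None]] = [
    ("acetanilide", "CC(=O)Nc1ccccc1", HPLC, "standard_anilide", None),
    ("m-hydroxyacetanilide", "CC(=O)Nc1cccc(O)c1", HPLC, "standard_anilide", None),
    ("dichloropropionanilide", "CCC(=O)Nc1ccc(Cl)c(Cl)c1", HPLC, "standard_anilide", None),
    ("butyranilide", "CCCC(=O)Nc1ccccc1", HPLC, "standard_anilide", None),
    ("hexananilide", "CCCCCC(=O)Nc1ccccc1", HPLC, "standard_anilide", None),
    ("pivalanilide", "CC(C)(C)C(=O)Nc1ccccc1", HPLC, "standard_anilide", None),
    ("metoclopramide-like", "CCNC(=O)c1cc(Cl)c(N)cc1OC", HPLC, "treat_as_anilide", None),
    ("sulfoacetanilide", "CC(=O)Nc1ccc(S(=O)(=O)[O-])cc1", HPLC, "standard_anilide", None),
    ("ammoniomethylacetanilide", "CC(=O)Nc1ccc(C[NH3+])cc1", HPLC, "standard_anilide", None),
    ("benzamide", "NC(=O)c1ccccc1", HPLC, "primary_amide_rule", None),
    ("4-nitrobenzamide", "NC(=O)c1ccc([N+](=O)[O-])cc1", HPLC, "primary_amide_rule", None),
    ("acesulfame", "CC1=CC(=O)NS(=O)(=O)O1", HPLC, "acesulfame_rule", None),
    ("4NP-butyrate", "CCCC(=O)Oc1ccc([N+](=O)[O-])cc1", COLORIMETRIC, "ester_as_amide", 100.0),
    (
        "4NP-trimethylacetate",
        "CC(C)(C)C(=O)Oc1ccc([N+](=O)[O-])cc1",
        COLORIMETRIC,
        "ester_as_amide",
        600.0,
    ),
    ("nitroacetanilide", "CC(=O)Nc1ccc([N+](=O)[O-])cc1", COLORIMETRIC, "standard_anilide", 1250.0),
    (
        "flutamide-like",
        "CC(C)C(=O)Nc1ccc([N+](=O)[O-])c(C(F)(F)F)c1",
        COLORIMETRIC,
        "standard_anilide",
        1250.0,
    ),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1", COLORIMETRIC, "standard_anilide", 2600.0),
]

_RING_SUBSTITUENTS = ["", "O", "Cl", "F", "OC", "[N+](=O)[O-]", "C", "CC", "S(=O)(=O)[O-]", "C[NH3+]"]

GENUS_POOL = [
    "Lacticaseibacillus",
    "Corynebacterium",
    "Gordonia",
    "Streptococcus",
    "Aerococcus",
    "Enterococcus",
    "Staphylococcus",
    "Actinomyces",
]


class SyntheticError(ValueError):
    """Raised for invalid synthetic configurations."""


class PlantedEnzymeEffect(BaseModel):
    """One planted alignment column: its 0-based column, which Atchley
    factor (1..4) carries the effect, and the logit-scale effect size on
    the standardized factor value."""

    model_config = {"extra": "forbid"}
    column: int
    factor: int = Field(ge=1, le=4)
    effect: float


class PlantedChemicalEffects(BaseModel):
    """Logit-scale coefficients on standardized chemical descriptors."""

    model_config = {"extra": "forbid"}
    mw_bond: float = -3.0
    mw: float = 0.0
    formal_charge: float = 2.0


class SyntheticConfig(BaseModel):
    """Full description of one synthetic study.

    Defaults emulate the modelling-scale screen: 16 active enzymes by a
    17-compound panel, a 200-column alignment whose 160-column signature
    region spans columns 20-180, triad serines at columns 114 and 138
    and the lysine at 60, the Gly/Ser motif at columns 95-107, one
    planted enzyme column carrying a molecular-size (factor 3) effect,
    and strong chemical effects favouring small amide tails and charged
    aryl substituents.
    """

    model_config = {"extra": "forbid"}

    n_enzymes: int = 16
    n_substrates: int = 17
    alignment_length: int = 200
    signature_span: tuple[int, int] = (20, 180)
    triad_columns: tuple[int, int, int] = (114, 138, 60)  # residues S, S, K
    motif_columns: tuple[int, int] = (95, 107)
    planted_enzyme_columns: list[PlantedEnzymeEffect] = Field(
        default_factory=lambda: [PlantedEnzymeEffect(column=150, factor=3, effect=2.5)]
    )
    planted_chemical_effects: PlantedChemicalEffects = Field(
        default_factory=PlantedChemicalEffects
    )
    intercept: float = -0.5
    n_variable_columns: int = 40
    n_gap_columns: int = 2
    n_replicates: int = 3
    deterministic_activity: bool = False
    # measurement model
    noise_sd_hplc: float = 0.05  # lognormal sigma on peak areas
    noise_sd_plate: float = 0.01  # additive OD noise
    control_removal_sd: float = 5.0  # percent, inactive/control removals
    active_removal_mean: float = 85.0  # percent
    active_removal_sd: float = 3.0  # percent, replicate-level
    hplc_base_area: float = 1000.0
    od_reference: float = 1.0
    plate_self_hydrolysis: float = 0.02  # fraction of reference at t_eval
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "SyntheticConfig":
        if min(self.n_enzymes, self.n_substrates, self.n_replicates) <= 0:
            raise SyntheticError("all counts must be positive")
        if self.alignment_length < 160:
            raise SyntheticError("alignment_length must be at least 160 columns")
        lo, hi = self.signature_span
        if not (0 <= lo < hi <= self.alignment_length):
            raise SyntheticError("signature_span outside the alignment")
        reserved = set(self.triad_columns) | set(range(*self.motif_columns))
        if len(set(self.triad_columns)) != 3:
            raise SyntheticError("triad columns must be three distinct columns")
        if any(c in range(*self.motif_columns) for c in self.triad_columns):
            raise SyntheticError("triad columns overlap the motif span")
        for p in self.planted_enzyme_columns:
            if p.column in reserved:
                raise SyntheticError(
                    f"planted column {p.column} overlaps a conserved triad/motif column"
                )
            if not 0 <= p.column < self.alignment_length:
                raise SyntheticError(f"planted column {p.column} outside the alignment")
        if any(c < 0 or c >= self.alignment_length for c in self.triad_columns):
            raise SyntheticError("triad columns outside the alignment")
        return self


@dataclass
class EnzymeRecord:
    """A candidate enzyme of the synthetic library."""

    enzyme_id: str
    genus: str
    sequence: str  # ungapped amino-acid sequence
    identity_to_query: float | None = None
    annotations: dict = field(default_factory=dict)


@dataclass
class SubstrateRecord:
    """A screened compound."""

    substrate_id: str
    smiles: str
    route: str
    special_case: str
    evaluation_time: float | None = None


@dataclass
class GroundTruth:
    """Planted activity with its generating probabilities."""

    activity: pd.DataFrame  # 0/1, enzymes x substrates
    activation_probability: pd.DataFrame
    planted_feature_names: list[str]
    substrates: list[SubstrateRecord]


def _rng(cfg: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


# ---------------------------------------------------------------------------
# Enzymes
# ---------------------------------------------------------------------------

def generate_enzyme_set(cfg: SyntheticConfig) -> tuple[dict[str, str], list[EnzymeRecord]]:
    """Generate the gapped alignment and enzyme records.

    Triad columns carry fixed S/S/K residues, the motif span is a
    conserved Gly/Ser pattern, planted and variable columns vary across
    enzymes (planted columns are resampled until at least two residues
    differ), and a few columns outside the signature region carry gaps.
    """
    rng = _rng(cfg, _STAGE_ENZYMES)
    L = cfg.alignment_length
    ids = [f"P{100 + i}" for i in range(cfg.n_enzymes)]
    triad_res = dict(zip(cfg.triad_columns, "SSK"))
    motif = set(range(*cfg.motif_columns))
    planted = {p.column for p in cfg.planted_enzyme_columns}
    reserved = set(cfg.triad_columns) | motif | planted

    free = [c for c in range(L) if c not in reserved]
    rng.shuffle(free)
    n_var = min(cfg.n_variable_columns, len(free))
    variable = set(free[:n_var])
    sig_lo, sig_hi = cfg.signature_span
    outside = [c for c in free[n_var:] if not sig_lo <= c < sig_hi]
    gap_cols = set(outside[: cfg.n_gap_columns])

    columns: list[list[str]] = []
    for c in range(L):
        if c in triad_res:
            columns.append([triad_res[c]] * cfg.n_enzymes)
        elif c in motif:
            res = str(rng.choice(["G", "S"], p=[0.6, 0.4]))
            columns.append([res] * cfg.n_enzymes)
        elif c in planted or c in variable:
            while True:
                col = [str(r) for r in rng.choice(list(AMINO_ACIDS), size=cfg.n_enzymes)]
                if len(set(col)) >= 2 or cfg.n_enzymes == 1:
                    break
            columns.append(col)
        elif c in gap_cols:
            col = [
                "-" if rng.random() < 0.3 else str(rng.choice(BACKGROUND_ALPHABET))
                for _ in range(cfg.n_enzymes)
            ]
            columns.append(col)
        else:
            columns.append([str(rng.choice(BACKGROUND_ALPHABET))] * cfg.n_enzymes)

    alignment = {
        ids[i]: "".join(columns[c][i] for c in range(L)) for i in range(cfg.n_enzymes)
    }
    records = [
        EnzymeRecord(
            enzyme_id=eid,
            genus=GENUS_POOL[i % len(GENUS_POOL)],
            sequence=alignment[eid].replace("-", ""),
        )
        for i, eid in enumerate(ids)
    ]
    return alignment, records


# ---------------------------------------------------------------------------
# Substrates
# ---------------------------------------------------------------------------

def _extra_anilides(n: int) -> list[tuple[str, str, str, str, float | None]]:
    """Enumerated para/meta-substituted anilides beyond the curated panel,
    spanning acyl chain lengths (hence amide-tail masses)."""
    out = []
    i = 0
    for meta in (False, True):
        for chain in range(50):
            for sub in _RING_SUBSTITUENTS:
                if len(out) >= n:
                    return out
                acyl = "C" * chain
                if sub:
                    ring = f"c1cccc({sub})c1" if meta else f"c1ccc({sub})cc1"
                else:
                    ring = "c1ccccc1"
                out.append(
                    (f"anilide-x{i}", f"{acyl}C(=O)N{ring}", HPLC, "standard_anilide", None)
                )
                i += 1
    if len(out) < n:
        raise SyntheticError(f"cannot enumerate {n} extra substrates")
    return out


def generate_substrate_set(cfg: SyntheticConfig) -> list[SubstrateRecord]:
    """Return ``cfg.n_substrates`` substrate records.

    The first records come from the curated template panel (anilides,
    aryl esters, primary amides, an acesulfame analogue); requests beyond
    the panel are filled with enumerated substituted anilides.
    """
    templates = list(CURATED_SUBSTRATES[: cfg.n_substrates])
    if cfg.n_substrates > len(CURATED_SUBSTRATES):
        templates += _extra_anilides(cfg.n_substrates - len(CURATED_SUBSTRATES))
    return [
        SubstrateRecord(
            substrate_id=name, smiles=smi, route=route, special_case=case, evaluation_time=t
        )
        for name, smi, route, case, t in templates
    ]


def substrates_to_frame(substrates: list[SubstrateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "substrate_id": [s.substrate_id for s in substrates],
            "smiles": [s.smiles for s in substrates],
            "route": [s.route for s in substrates],
            "special_case": [s.special_case for s in substrates],
            "evaluation_time": [s.evaluation_time for s in substrates],
        }
    )


# ---------------------------------------------------------------------------
# Planted activity
# ---------------------------------------------------------------------------

def _standardize(values: np.ndarray, name: str) -> np.ndarray:
    sd = float(np.std(values))
    if sd == 0:
        raise SyntheticError(f"descriptor {name!r} has zero variance; cannot standardize")
    return (values - float(np.mean(values))) / sd


def plant_activity_model(
    alignment: dict[str, str],
    substrates: list[SubstrateRecord],
    cfg: SyntheticConfig,
) -> GroundTruth:
    """Plant the logistic activity rule and sample the activity matrix.

    ``P(active) = sigmoid(intercept + sum(chemical effects x standardized
    descriptors) + sum(enzyme effects x standardized Atchley values at
    planted columns))``.  Descriptors with a zero coefficient do not
    enter the model and are exempt from the zero-variance check.
    Activity is Bernoulli-sampled unless ``cfg.deterministic_activity``,
    which thresholds the probability at 0.5 for exact-recovery tests.
    """
    rng = _rng(cfg, _STAGE_ACTIVITY)
    enzyme_ids = list(alignment)
    substrate_ids = [s.substrate_id for s in substrates]

    descriptors = {"MW_bond": [], "MW": [], "formal_charge_count": []}
    for s in substrates:
        feats = chemical_descriptors(s.smiles, s.special_case).values
        for k in descriptors:
            descriptors[k].append(feats[k])
    coeffs = {
        "MW_bond": cfg.planted_chemical_effects.mw_bond,
        "MW": cfg.planted_chemical_effects.mw,
        "formal_charge_count": cfg.planted_chemical_effects.formal_charge,
    }
    chem_term = np.zeros(len(substrates))
    planted_names = []
    for name, coef in coeffs.items():
        if coef == 0:
            continue
        chem_term += coef * _standardize(np.asarray(descriptors[name], float), name)
        planted_names.append(name)

    enz_term = np.zeros(len(enzyme_ids))
    for p in cfg.planted_enzyme_columns:
        if p.effect == 0:
            continue
        vals = np.array(
            [
                ATCHLEY_FACTORS[alignment[e][p.column]][p.factor - 1]
                if alignment[e][p.column] != "-"
                else 0.0
                for e in enzyme_ids
            ]
        )
        enz_term += p.effect * _standardize(vals, f"AA{p.column + 1}_f{p.factor}")
        planted_names.append(f"AA{p.column + 1}_f{p.factor}")

    logit = cfg.intercept + enz_term[:, None] + chem_term[None, :]
    prob = 1.0 / (1.0 + np.exp(-logit))
    if cfg.deterministic_activity:
        activity = (prob > 0.5).astype(int)
    else:
        activity = (rng.random(prob.shape) < prob).astype(int)
    return GroundTruth(
        activity=pd.DataFrame(activity, index=enzyme_ids, columns=substrate_ids),
        activation_probability=pd.DataFrame(prob, index=enzyme_ids, columns=substrate_ids),
        planted_feature_names=planted_names,
        substrates=list(substrates),
    )


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------

def simulate_measurements(truth: GroundTruth, cfg: SyntheticConfig) -> pd.DataFrame:
    """Simulate the long-format measurement table for both assay routes.

    HPLC substrates get per-replicate t0/t24 peak areas with
    multiplicative lognormal noise; active pairs draw their removal from
    the high-removal distribution, inactive pairs and the dead-enzyme
    control from a near-zero one.  Colorimetric substrates get OD series
    on a fixed time grid: active pairs approach the complete-turnover
    reference exponentially (95% converted at the evaluation time),
    inactive pairs and the control follow the slow self-hydrolysis
    drift.  Reference replicates carry the 100% turnover OD.
    """
    rng = _rng(cfg, _STAGE_MEASUREMENTS)
    rows = []
    enzyme_ids = list(truth.activity.index)
    reps = range(1, cfg.n_replicates + 1)

    def hplc_rows(substrate_id):
        for enzyme_id in enzyme_ids + [CONTROL_ENZYME_ID]:
            is_control = enzyme_id == CONTROL_ENZYME_ID
            active = (not is_control) and truth.activity.at[enzyme_id, substrate_id] == 1
            for rep in reps:
                if active:
                    removal = rng.normal(cfg.active_removal_mean, cfg.active_removal_sd)
                else:
                    removal = rng.normal(0.0, cfg.control_removal_sd)
                removal = min(removal, 99.5)
                noise0 = math.exp(rng.normal(0.0, cfg.noise_sd_hplc)) if cfg.noise_sd_hplc else 1.0
                noise1 = math.exp(rng.normal(0.0, cfg.noise_sd_hplc)) if cfg.noise_sd_hplc else 1.0
                a0 = cfg.hplc_base_area * noise0
                # t24 shares the t0 scale so the noise-free round trip is exact
                a24 = a0 * (1.0 - removal / 100.0) * noise1
                rows.append((enzyme_id, substrate_id, rep, HPLC, 0.0, a0, is_control, False))
                rows.append((enzyme_id, substrate_id, rep, HPLC, 24.0, a24, is_control, False))

    def plate_rows(substrate_id, t_eval):
        tau = t_eval / 3.0  # ~95% conversion at the evaluation time
        for enzyme_id in enzyme_ids + [CONTROL_ENZYME_ID]:
            is_control = enzyme_id == CONTROL_ENZYME_ID
            active = (not is_control) and truth.activity.at[enzyme_id, substrate_id] == 1
            for rep in reps:
                for t in PLATE_TIME_GRID:
                    if active:
                        od = cfg.od_reference * (1.0 - math.exp(-t / tau))
                    else:
                        od = cfg.od_reference * cfg.plate_self_hydrolysis * (t / t_eval)
                    if cfg.noise_sd_plate:
                        od += rng.normal(0.0, cfg.noise_sd_plate)
                    rows.append(
                        (enzyme_id, substrate_id, rep, COLORIMETRIC, t, od, is_control, False)
                    )
        for rep in reps:
            for t in PLATE_TIME_GRID:
                od = cfg.od_reference
                if cfg.noise_sd_plate:
                    od += rng.normal(0.0, cfg.noise_sd_plate)
                rows.append(
                    (REFERENCE_ID, substrate_id, rep, COLORIMETRIC, t, od, False, True)
                )

    for s in truth.substrates:
        if s.route == HPLC:
            hplc_rows(s.substrate_id)
        else:
            t_eval = s.evaluation_time if s.evaluation_time is not None else 600.0
            plate_rows(s.substrate_id, t_eval)
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


# ---------------------------------------------------------------------------
# Convenience
# ---------------------------------------------------------------------------

def default_hitcalling_config(substrates: list[SubstrateRecord]) -> HitCallingConfig:
    """Hit-calling configuration matched to a generated substrate panel."""
    return HitCallingConfig(
        evaluation_times={
            s.substrate_id: (s.evaluation_time if s.evaluation_time is not None else 600.0)
            for s in substrates
            if s.route == COLORIMETRIC
        },
        ester_substrates=[s.substrate_id for s in substrates if s.special_case == "ester_as_amide"],
        control_enzyme_id=CONTROL_ENZYME_ID,
    )


def generate_homolog_set(
    n_hits: int = 50,
    seed: int = 0,
    n_families: int = 5,
    query_length: int = 300,
):
    """Synthetic homolog search results for the library-design stage.

    Builds a query sequence containing the family "GSS" motif, derives
    ``n_families`` diverged family seeds from it, and samples hits
    around those seeds with realistic annotation structure: a few
    near-query duplicates (>90 % identity), a few motif-less sequences,
    occasional glutamyl-tRNA-synthetase EC predictions, literature
    flags, repeated genera, and a minority of hits failing the
    significance cutoffs.  Returns ``(hits, query_sequence)`` with hits
    as :class:`~amidasekit.library_design.HomologHit` records.
    """
    from .library_design import HomologHit

    rng = np.random.default_rng([seed, 7])
    letters = list(AMINO_ACIDS)

    def random_seq(n):
        return "".join(rng.choice(letters, size=n))

    def mutate(seq, rate):
        out = []
        for ch in seq:
            if rng.random() < rate:
                out.append(str(rng.choice([l for l in letters if l != ch])))
            else:
                out.append(ch)
        return "".join(out)

    def plant_motif(seq):
        at = len(seq) // 2
        return seq[:at] + "GSS" + seq[at + 3 :]

    query = plant_motif(random_seq(query_length))
    family_seeds = [plant_motif(mutate(query, 0.55)) for _ in range(n_families)]

    hits = []
    for i in range(n_hits):
        sid = f"H{i:03d}"
        kind = rng.random()
        if kind < 0.08:  # near-duplicate of the query
            seq = plant_motif(mutate(query, 0.02))
        else:
            seq = plant_motif(mutate(family_seeds[i % n_families], float(rng.uniform(0.05, 0.2))))
            trim = int(rng.integers(0, 12))
            if trim:
                seq = seq[trim // 2 : len(seq) - (trim - trim // 2)]
        if rng.random() < 0.15:  # destroy the family motif
            seq = seq.replace("GSS", "GAA")
        if rng.random() < 0.85:
            e_value = float(10.0 ** -rng.uniform(1, 50))
            cover = float(rng.uniform(60, 100))
            bits = float(rng.uniform(80, 500))
        else:  # fails at least one significance cutoff
            e_value = float(rng.uniform(0.15, 5.0))
            cover = float(rng.uniform(5, 15))
            bits = float(rng.uniform(10, 45))
        hits.append(
            HomologHit(
                query_id="QUERY",
                subject_id=sid,
                e_value=e_value,
                query_cover=cover,
                bitscore=bits,
                subject_sequence=seq,
                genus=str(rng.choice(GENUS_POOL)),
                predicted_ec="6.3.5.7" if rng.random() < 0.1 else "3.5.1.13",
                excluded_by_literature=bool(rng.random() < 0.05),
            )
        )
    return hits, query


def generate_study(cfg: SyntheticConfig):
    """Run all generator stages; returns (alignment, enzyme records,
    substrates, ground truth, measurements)."""
    alignment, enzymes = generate_enzyme_set(cfg)
    substrates = generate_substrate_set(cfg)
    truth = plant_activity_model(alignment, substrates, cfg)
    measurements = simulate_measurements(truth, cfg)
    return alignment, enzymes, substrates, truth, measurements


def write_run(cfg: SyntheticConfig, out_dir) -> dict[str, str]:
    """Write all synthetic artifacts under ``out_dir``; returns paths."""
    from pathlib import Path

    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    alignment, enzymes, substrates, truth, measurements = generate_study(cfg)
    paths = {}
    aln_path = out / "alignment.fasta"
    SeqIO.write(
        [SeqRecord(Seq(seq), id=eid, description="") for eid, seq in alignment.items()],
        aln_path,
        "fasta",
    )
    paths["alignment"] = str(aln_path)
    sub_path = out / "substrates.tsv"
    substrates_to_frame(substrates).to_csv(sub_path, sep="\t", index=False)
    paths["substrates"] = str(sub_path)
    meas_path = out / "measurements.csv"
    measurements.to_csv(meas_path, index=False)
    paths["measurements"] = str(meas_path)
    truth_path = out / "ground_truth.csv"
    truth.activity.to_csv(truth_path, index_label="enzyme_id")
    paths["ground_truth"] = str(truth_path)
    prob_path = out / "activation_probability.csv"
    truth.activation_probability.to_csv(prob_path, index_label="enzyme_id")
    paths["activation_probability"] = str(prob_path)
    return paths
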