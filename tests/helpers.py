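"""Independent reference implementations used as test oracles.

Everything here is deliberately written as plain per-cell / per-rule
loops, independent of the vectorized package code paths it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd

from amidasekit.hitcalling import COLORIMETRIC, HPLC, MEASUREMENT_COLUMNS, HitCallingConfig
from amidasekit.library_design import pairwise_identity


# ---------------------------------------------------------------------------
# Naive hit calling
# ---------------------------------------------------------------------------

def quantile_linear(values, q):
    """Type-7 (linear interpolation) quantile, written from scratch."""
    xs = sorted(values)
    if len(xs) == 1:
        return xs[0]
    h = (len(xs) - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def median(values):
    return quantile_linear(values, 0.5)


def sd_sample(values):
    if len(values) < 2:
        return 0.0
    m = sum(values) / len(values)
    return math.sqrt(sum((v - m) ** 2 for v in values) / (len(values) - 1))


def naive_call_hits(measurements: pd.DataFrame, cfg: HitCallingConfig) -> dict:
    """Per-cell reference applying the quoted hit rules with plain loops."""
    decisions = {}
    for substrate_id in sorted(measurements["substrate_id"].unique()):
        sub = measurements[measurements["substrate_id"] == substrate_id]
        route = sub["route"].iloc[0]
        if route == HPLC:
            removals = {}
            for (enzyme_id, rep), grp in sub.groupby(["enzyme_id", "replicate"]):
                a0 = float(grp[grp["time"] == 0.0]["value"].iloc[0])
                a24 = float(grp[grp["time"] == 24.0]["value"].iloc[0])
                removals[(enzyme_id, rep)] = 100.0 * (a0 - a24) / a0
            ctrl_ids = set(sub[sub["is_control"]]["enzyme_id"])
            ctrl = [v for (e, r), v in removals.items() if e in ctrl_ids]
            q1, q3 = quantile_linear(ctrl, 0.25), quantile_linear(ctrl, 0.75)
            iqr = q3 - q1
            lo = q1 - cfg.control_fence_multiplier * iqr
            hi = q3 + cfg.control_fence_multiplier * iqr
            kept = [v for v in ctrl if lo <= v <= hi]
            k1, k3 = quantile_linear(kept, 0.25), quantile_linear(kept, 0.75)
            stat = median(kept) + cfg.hit_iqr_multiplier * (k3 - k1)
            for enzyme_id in sorted(sub[~sub["is_control"]]["enzyme_id"].unique()):
                meds = [v for (e, r), v in removals.items() if e == enzyme_id]
                med = median(meds)
                decisions[(enzyme_id, substrate_id)] = int(
                    med > stat and med > cfg.hplc_removal_threshold
                )
        else:
            t_eval = cfg.evaluation_times[substrate_id]
            at_t = sub[sub["time"] == t_eval]
            ref = [float(v) for v in at_t[at_t["is_reference"]]["value"]]
            ref_mean = sum(ref) / len(ref)
            ctrl_rows = at_t[at_t["is_control"] & ~at_t["is_reference"]]
            ctrl_yields = [100.0 * float(v) / ref_mean for v in ctrl_rows["value"]]
            ctrl_mean = sum(ctrl_yields) / len(ctrl_yields)
            thr = ctrl_mean + cfg.plate_sd_multiplier * sd_sample(ctrl_yields)
            is_ester = substrate_id in cfg.ester_substrates
            samples = at_t[~at_t["is_control"] & ~at_t["is_reference"]]
            for enzyme_id in sorted(samples["enzyme_id"].unique()):
                ys = [
                    100.0 * float(v) / ref_mean
                    for v in samples[samples["enzyme_id"] == enzyme_id]["value"]
                ]
                m = sum(ys) / len(ys)
                hit = m >= thr and m > ctrl_mean
                if is_ester:
                    hit = hit and m > cfg.ester_yield_threshold
                decisions[(enzyme_id, substrate_id)] = int(hit)
    return decisions


def random_measurement_table(rng: np.random.Generator):
    """A small randomized mixed-route measurement table plus its config."""
    n_enzymes = int(rng.integers(2, 5))
    n_substrates = int(rng.integers(2, 5))
    n_reps = int(rng.integers(3, 7))
    enzymes = [f"E{i}" for i in range(n_enzymes)]
    substrates = [f"S{j}" for j in range(n_substrates)]
    routes = [HPLC if rng.random() < 0.6 else COLORIMETRIC for _ in substrates]
    if COLORIMETRIC not in routes:
        routes[-1] = COLORIMETRIC
    if HPLC not in routes:
        routes[0] = HPLC
    grid = [0.0, 60.0, 120.0]
    eval_times = {}
    esters = []
    rows = []
    for substrate_id, route in zip(substrates, routes):
        if route == HPLC:
            constant_ctrl = rng.random() < 0.1
            for enzyme_id in enzymes + ["CTRL"]:
                for rep in range(1, n_reps + 1):
                    a0 = float(rng.uniform(500, 1500))
                    if enzyme_id == "CTRL" and constant_ctrl:
                        a0, a24 = 1000.0, 950.0
                    else:
                        a24 = a0 * float(rng.uniform(0.0, 1.3))
                    rows.append(
                        (enzyme_id, substrate_id, rep, HPLC, 0.0, a0, enzyme_id == "CTRL", False)
                    )
                    rows.append(
                        (enzyme_id, substrate_id, rep, HPLC, 24.0, a24, enzyme_id == "CTRL", False)
                    )
        else:
            eval_times[substrate_id] = float(rng.choice(grid[1:]))
            if rng.random() < 0.5:
                esters.append(substrate_id)
            tie_to_control = rng.random() < 0.1
            for enzyme_id in enzymes + ["CTRL"]:
                for rep in range(1, n_reps + 1):
                    for t in grid:
                        if tie_to_control:
                            od = 0.3 + 0.01 * t  # exact ties across enzymes
                        else:
                            od = float(rng.uniform(0.0, 1.2))
                        rows.append(
                            (
                                enzyme_id,
                                substrate_id,
                                rep,
                                COLORIMETRIC,
                                t,
                                od,
                                enzyme_id == "CTRL",
                                False,
                            )
                        )
            for rep in range(1, n_reps + 1):
                for t in grid:
                    rows.append(
                        ("REF", substrate_id, rep, COLORIMETRIC, t, float(rng.uniform(0.8, 1.2)), False, True)
                    )
    cfg = HitCallingConfig(
        evaluation_times=eval_times, ester_substrates=esters, control_enzyme_id="CTRL"
    )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS), cfg


# ---------------------------------------------------------------------------
# Brute-force library selection
# ---------------------------------------------------------------------------

def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def brute_force_maxmin_subset(profiles: dict[str, str], keep: int, anchor=None):
    """Exhaustive max-min Hamming subset selection (ties: smallest tuple)."""
    members = sorted(profiles)
    if keep >= len(members):
        return members

    def min_pairwise(subset):
        if len(subset) < 2:
            return math.inf
        return min(hamming(profiles[a], profiles[b]) for a, b in combinations(subset, 2))

    pool = [s for s in combinations(members, keep) if anchor is None or anchor in s]
    best = min(pool, key=lambda s: (-min_pairwise(s), s))
    return sorted(best)


def oracle_select_library(hits, query_sequence, threshold=60.0):
    """Rule-by-rule scripted re-application of the selection procedure,
    independent of the package's pipeline code."""
    ok = [
        h
        for h in hits
        if h.e_value <= 0.1 and h.query_cover >= 20.0 and h.bitscore >= 50.0
    ]
    ok = sorted(ok, key=lambda h: (h.e_value, h.subject_id))
    by_seq = {}
    for h in ok:
        by_seq.setdefault(h.subject_sequence, h)
    kept = sorted(by_seq.values(), key=lambda h: h.subject_id)
    seqs = {h.subject_id: h.subject_sequence for h in kept}
    ann = {h.subject_id: h for h in kept}

    # greedy clustering: longest first, lexicographic ties
    order = sorted(seqs, key=lambda s: (-len(seqs[s]), s))
    clusters = []  # (rep_id, [member ids])
    ident_cache = {}

    def ident(a, b):
        if (a, b) not in ident_cache:
            ident_cache[(a, b)] = pairwise_identity(seqs[a], seqs[b])
        return ident_cache[(a, b)]

    for sid in order:
        for cl in clusters:
            if ident(sid, cl[0]) >= threshold:
                cl[1].append(sid)
                break
        else:
            clusters.append((sid, [sid]))

    from amidasekit.library_design import _profiles_against_representative

    pooled = []
    for rep_id, member_ids in clusters:
        members = [
            sid
            for sid in sorted(member_ids)
            if pairwise_identity(seqs[sid], query_sequence) <= 90.0 and "GSS" in seqs[sid]
        ]
        if not members:
            continue
        keep = math.ceil(len(members) / 2)
        profiles = _profiles_against_representative(members, seqs, rep_id)
        anchor = rep_id if rep_id in members else None
        chosen = brute_force_maxmin_subset(
            {m: profiles[m] for m in members}, keep, anchor=anchor
        )
        best_by_genus = {}
        for sid in chosen:
            g = ann[sid].genus
            cur = best_by_genus.get(g)
            if cur is None or (
                -pairwise_identity(seqs[sid], query_sequence),
                sid,
            ) < (-pairwise_identity(seqs[cur], query_sequence), cur):
                best_by_genus[g] = sid
        pooled.extend(best_by_genus.values())

    pooled = [sid for sid in pooled if ann[sid].predicted_ec != "6.3.5.7"]
    by_genus = {}
    for sid in pooled:
        by_genus.setdefault(ann[sid].genus, []).append(sid)
    capped = []
    for genus, sids in by_genus.items():
        ranked = sorted(sids, key=lambda s: (-pairwise_identity(seqs[s], query_sequence), s))
        capped.extend(ranked[:3])
    final = sorted(sid for sid in capped if not ann[sid].excluded_by_literature)
    return final
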