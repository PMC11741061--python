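"""Diversity-driven selection of a candidate enzyme library from
homolog search hits.

The procedure mirrors how a screening library is assembled from a
protein homology search: hits are kept when they clear significance
cutoffs (e-value <= 0.1, query cover >= 20 %, bitscore >= 50), unique
subject sequences are greedily clustered at 60 % amino-acid identity,
and each cluster is then thinned to maximize sequence diversity while
honouring biological bookkeeping rules:

1. drop sequences over 90 % identical to the query (nothing new);
2. drop sequences lacking the family's "GSS" motif;
3. within each cluster, keep at most half the members (``ceil(n/2)``),
   chosen to maximize the minimum pairwise Hamming distance between the
   kept members (computed on per-cluster alignments to the cluster
   representative; gap-vs-residue counts as a mismatch);
4. within each cluster, keep only the highest-identity-to-query member
   per genus;
5. pool the clusters and drop predicted EC 6.3.5.7 sequences
   (glutamyl-tRNA synthetases picked up by the amidase search);
6. cap each genus at three sequences, keeping the highest identity to
   the query;
7. drop sequences flagged as already characterized in the literature
   (an input annotation; literature search itself is out of scope).

Identity follows the clustering convention: global alignment (BLOSUM62,
gap open 10 / extend 0.5), identical aligned residues divided by the
shorter sequence length.

For clusters of up to ``EXACT_DOWNSAMPLE_LIMIT`` members the Hamming
downsampling enumerates all subsets and returns the exact max-min
optimum (anchored on the representative when it is still present);
larger clusters fall back to greedy farthest-point selection, which
approximates the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
EXACT_DOWNSAMPLE_LIMIT = 10
EC_TRNA_SYNTHETASE = "6.3.5.7"
FAMILY_MOTIF = "GSS"


class LibraryDesignError(ValueError):
    """Raised on malformed inputs to the library-design stage."""


@dataclass
class HomologHit:
    """One homolog search hit with its selection-relevant annotations."""

    query_id: str
    subject_id: str
    e_value: float
    query_cover: float
    bitscore: float
    subject_sequence: str
    genus: str | None = None
    predicted_ec: str | None = None
    excluded_by_literature: bool = False


@dataclass
class Cluster:
    """A greedy identity cluster."""

    representative_id: str
    member_ids: list[str]
    identity_cache: dict = field(default_factory=dict)


@dataclass
class SelectedEnzyme:
    """A library member that survived all selection rules."""

    enzyme_id: str
    genus: str
    sequence: str
    identity_to_query: float
    cluster_id: str


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity under the clustering convention.

    Global alignment; identity = identical aligned residues / length of
    the shorter sequence x 100.
    """
    for seq in (seq_a, seq_b):
        if not seq:
            raise LibraryDesignError("cannot align an empty sequence")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise LibraryDesignError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    aln = _aligner().align(seq_a, seq_b)[0]
    blocks_a, blocks_b = aln.aligned
    matches = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        matches += sum(1 for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]) if x == y)
    return 100.0 * matches / min(len(seq_a), len(seq_b))


# ---------------------------------------------------------------------------
# Hit filtering and clustering
# ---------------------------------------------------------------------------

def read_blast_hits(path, sequences: dict[str, str], annotations: pd.DataFrame) -> list[HomologHit]:
    """Parse a header-less outfmt-6-style TSV.

    Expected columns: query_id, subject_id, e_value, query_cover,
    bitscore.  ``sequences`` maps subject ids to amino-acid sequences;
    ``annotations`` carries id, genus, predicted_ec, excluded columns.
    """
    ann = annotations.set_index("id") if "id" in annotations.columns else annotations
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise LibraryDesignError(f"malformed hit row at line {lineno}: {line!r}")
            try:
                qid, sid = parts[0], parts[1]
                e, cover, bits = float(parts[2]), float(parts[3]), float(parts[4])
            except ValueError as err:
                raise LibraryDesignError(f"malformed hit row at line {lineno}: {err}") from None
            row = ann.loc[sid] if sid in ann.index else None
            hits.append(
                HomologHit(
                    query_id=qid,
                    subject_id=sid,
                    e_value=e,
                    query_cover=cover,
                    bitscore=bits,
                    subject_sequence=sequences.get(sid, ""),
                    genus=None if row is None else row.get("genus"),
                    predicted_ec=None if row is None else (row.get("predicted_ec") or None),
                    excluded_by_literature=bool(row.get("excluded")) if row is not None else False,
                )
            )
    return hits


def filter_blast_hits(
    hits: list[HomologHit],
    e_max: float = 0.1,
    cover_min: float = 20.0,
    bitscore_min: float = 50.0,
) -> list[HomologHit]:
    """Keep hits meeting all cutoffs (boundaries inclusive) and
    deduplicate identical subject sequences, keeping the lowest e-value
    (ties: lexicographically first subject id)."""
    kept = [
        h
        for h in hits
        if h.e_value <= e_max and h.query_cover >= cover_min and h.bitscore >= bitscore_min
    ]
    kept.sort(key=lambda h: (h.e_value, h.subject_id))
    seen: dict[str, HomologHit] = {}
    for h in kept:
        if h.subject_sequence not in seen:
            seen[h.subject_sequence] = h
    out = list(seen.values())
    out.sort(key=lambda h: h.subject_id)
    return out


def greedy_cluster(sequences: dict[str, str], threshold: float = 60.0) -> list[Cluster]:
    """Greedy length-sorted identity clustering.

    Sequences are visited longest first (equal lengths: lexicographic id
    order); each joins the first existing cluster whose representative
    it matches at >= ``threshold`` percent identity, else founds a new
    cluster.
    """
    if not sequences:
        raise LibraryDesignError("no sequences to cluster")
    order = sorted(sequences, key=lambda sid: (-len(sequences[sid]), sid))
    clusters: list[Cluster] = []
    for sid in order:
        placed = False
        for cluster in clusters:
            rep_seq = sequences[cluster.representative_id]
            ident = cluster.identity_cache.get(sid)
            if ident is None:
                ident = pairwise_identity(sequences[sid], rep_seq)
                cluster.identity_cache[sid] = ident
            if ident >= threshold:
                cluster.member_ids.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative_id=sid, member_ids=[sid]))
    return clusters


# ---------------------------------------------------------------------------
# Hamming diversity downsampling
# ---------------------------------------------------------------------------

def _profiles_against_representative(
    member_ids: list[str], sequences: dict[str, str], representative_id: str
) -> dict[str, str]:
    """Project each member onto the representative's coordinates.

    Positions of the representative with no aligned member residue are
    gaps; member insertions relative to the representative are ignored.
    The representative's profile is itself.
    """
    rep_seq = sequences[representative_id]
    aligner = _aligner()
    profiles = {}
    for sid in member_ids:
        if sid == representative_id:
            profiles[sid] = rep_seq
            continue
        aln = aligner.align(rep_seq, sequences[sid])[0]
        profile = ["-"] * len(rep_seq)
        blocks_t, blocks_q = aln.aligned
        for (t0, t1), (q0, q1) in zip(blocks_t, blocks_q):
            profile[t0:t1] = sequences[sid][q0:q1]
        profiles[sid] = "".join(profile)
    return profiles


def hamming_distance(profile_a: str, profile_b: str) -> int:
    """Mismatch count over equal-length profiles; gap-vs-residue is a
    mismatch, gap-vs-gap is a match."""
    if len(profile_a) != len(profile_b):
        raise LibraryDesignError("Hamming distance requires equal-length profiles")
    return sum(1 for x, y in zip(profile_a, profile_b) if x != y)


def _min_pairwise(subset: tuple[str, ...], dist: dict) -> float:
    if len(subset) < 2:
        return math.inf
    return min(dist[a, b] for a, b in combinations(subset, 2))


def downsample_cluster(
    member_ids: list[str],
    profiles: dict[str, str],
    keep: int,
    anchor: str | None = None,
) -> list[str]:
    """Pick ``keep`` members maximizing the minimum pairwise Hamming
    distance.

    Exact subset enumeration for clusters of up to
    ``EXACT_DOWNSAMPLE_LIMIT`` members; greedy farthest-point selection
    (seeded on ``anchor``) beyond that.  Ties break on the
    lexicographically smallest member tuple.
    """
    members = sorted(member_ids)
    if keep >= len(members):
        return members
    dist = {
        (a, b): hamming_distance(profiles[a], profiles[b])
        for a, b in combinations(members, 2)
    }
    dist.update({(b, a): d for (a, b), d in list(dist.items())})
    if len(members) <= EXACT_DOWNSAMPLE_LIMIT:
        pool = [
            s
            for s in combinations(members, keep)
            if anchor is None or anchor in s
        ]
        best = min(pool, key=lambda s: (-_min_pairwise(s, dist), s))
        return sorted(best)
    chosen = [anchor if anchor in members else members[0]] if anchor else [members[0]]
    while len(chosen) < keep:
        remaining = [m for m in members if m not in chosen]
        nxt = min(remaining, key=lambda m: (-min(dist[m, c] for c in chosen), m))
        chosen.append(nxt)
    return sorted(chosen)


# ---------------------------------------------------------------------------
# Rule pipeline
# ---------------------------------------------------------------------------

def filter_and_downsample(
    clusters: list[Cluster],
    sequences: dict[str, str],
    query_sequence: str,
    annotations: dict[str, dict],
    identity_exclusion: float = 90.0,
    genus_cap: int = 3,
) -> tuple[list[SelectedEnzyme], pd.DataFrame]:
    """Apply selection rules 1-7 over the clustered hits.

    ``annotations[id]`` must provide ``genus`` and may provide
    ``predicted_ec`` and ``excluded``.  Returns the selected enzymes and
    a per-sequence report naming the rule that excluded each casualty.
    """
    report_rows = []
    identity_to_query: dict[str, float] = {}

    def ident(sid: str) -> float:
        if sid not in identity_to_query:
            identity_to_query[sid] = pairwise_identity(sequences[sid], query_sequence)
        return identity_to_query[sid]

    def genus_of(sid: str) -> str:
        ann = annotations.get(sid)
        if ann is None or not ann.get("genus"):
            raise LibraryDesignError(f"missing genus annotation for sequence {sid!r}")
        return ann["genus"]

    surviving: dict[str, list[str]] = {}
    for cluster in clusters:
        members = []
        for sid in sorted(cluster.member_ids):
            if ident(sid) > identity_exclusion:
                report_rows.append((sid, "excluded", "identity_to_query>90"))
            elif FAMILY_MOTIF not in sequences[sid]:
                report_rows.append((sid, "excluded", "missing_GSS_motif"))
            else:
                members.append(sid)
        if members:
            surviving[cluster.representative_id] = members

    pooled: list[tuple[str, str]] = []  # (sid, cluster representative)
    for rep_id, members in surviving.items():
        keep = math.ceil(len(members) / 2)
        profiles = _profiles_against_representative(members, sequences, rep_id)
        anchor = rep_id if rep_id in members else None
        kept = downsample_cluster(members, profiles, keep, anchor=anchor)
        for sid in members:
            if sid not in kept:
                report_rows.append((sid, "excluded", "hamming_downsampling"))
        by_genus: dict[str, list[str]] = {}
        for sid in kept:
            by_genus.setdefault(genus_of(sid), []).append(sid)
        for genus, sids in by_genus.items():
            best = min(sids, key=lambda s: (-ident(s), s))
            for sid in sids:
                if sid != best:
                    report_rows.append((sid, "excluded", "per_cluster_genus_dedup"))
            pooled.append((best, rep_id))

    after_ec = []
    for sid, rep_id in pooled:
        ann = annotations.get(sid, {})
        if (ann.get("predicted_ec") or "") == EC_TRNA_SYNTHETASE:
            report_rows.append((sid, "excluded", "predicted_EC_6.3.5.7"))
        else:
            after_ec.append((sid, rep_id))

    by_genus_global: dict[str, list[tuple[str, str]]] = {}
    for sid, rep_id in after_ec:
        by_genus_global.setdefault(genus_of(sid), []).append((sid, rep_id))
    after_cap = []
    for genus, entries in by_genus_global.items():
        ranked = sorted(entries, key=lambda e: (-ident(e[0]), e[0]))
        for sid, rep_id in ranked[:genus_cap]:
            after_cap.append((sid, rep_id))
        for sid, _ in ranked[genus_cap:]:
            report_rows.append((sid, "excluded", "genus_cap_3"))

    selected = []
    for sid, rep_id in sorted(after_cap):
        ann = annotations.get(sid, {})
        if ann.get("excluded"):
            report_rows.append((sid, "excluded", "literature_flag"))
            continue
        report_rows.append((sid, "selected", "passed_all_rules"))
        selected.append(
            SelectedEnzyme(
                enzyme_id=sid,
                genus=genus_of(sid),
                sequence=sequences[sid],
                identity_to_query=ident(sid),
                cluster_id=rep_id,
            )
        )
    report = pd.DataFrame(report_rows, columns=["sequence_id", "status", "rule"])
    return selected, report


def select_library(
    hits: list[HomologHit],
    query_sequence: str,
    annotations: dict[str, dict] | None = None,
    target_size: int | None = None,
    cluster_threshold: float = 60.0,
) -> tuple[list[SelectedEnzyme], pd.DataFrame]:
    """End-to-end library selection from raw homolog hits.

    Composes significance filtering, greedy clustering and the rule
    pipeline; annotations default to those carried on the hits.  With
    ``target_size`` the selection is capped, keeping the highest
    identity to the query.  Returns the library and the full selection
    report.
    """
    if annotations is None:
        annotations = {
            h.subject_id: {
                "genus": h.genus,
                "predicted_ec": h.predicted_ec,
                "excluded": h.excluded_by_literature,
            }
            for h in hits
        }
    kept = filter_blast_hits(hits)
    dropped = {h.subject_id for h in hits} - {h.subject_id for h in kept}
    report_rows = [(sid, "excluded", "blast_cutoffs_or_duplicate") for sid in sorted(dropped)]
    if not kept:
        return [], pd.DataFrame(report_rows, columns=["sequence_id", "status", "rule"])
    sequences = {h.subject_id: h.subject_sequence for h in kept}
    clusters = greedy_cluster(sequences, threshold=cluster_threshold)
    selected, report = filter_and_downsample(clusters, sequences, query_sequence, annotations)
    if target_size is not None and len(selected) > target_size:
        ranked = sorted(selected, key=lambda e: (-e.identity_to_query, e.enzyme_id))
        cut = {e.enzyme_id for e in ranked[target_size:]}
        report.loc[report["sequence_id"].isin(cut), ["status", "rule"]] = [
            "excluded",
            "target_size_cap",
        ]
        selected = [e for e in ranked[:target_size]]
        selected.sort(key=lambda e: e.enzyme_id)
    report = pd.concat(
        [pd.DataFrame(report_rows, columns=report.columns), report], ignore_index=True
    )
    return selected, report
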