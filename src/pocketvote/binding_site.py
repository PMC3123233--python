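"""Core binding-site inference: ligand contact graph, cluster selection,
and the residue voting rule.

After all accepted templates have deposited their ligands in the model
frame, two ligands are "in contact" when any pair of their heavy atoms is
within van der Waals distance plus a 0.5 Å margin.  The connected
components of this contact graph are the candidate binding pockets (a
single-linkage agglomeration with a contact linkage criterion yields
exactly these components); the largest component is taken as the most
likely pocket.  Each model residue then receives one vote per cluster
ligand it touches, and a residue enters the final prediction iff it
contacts at least 2 ligands AND at least 25% of the cluster.  The 25%
boundary is inclusive and evaluated in exact integer arithmetic, so a
residue with exactly a quarter of the votes is never lost to floating
point.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .errors import ClusteringError, InputError
from .structure_io import DEFAULT_VDW, Ligand, Residue, StructureModel, VdWTable
from .superposition import SuperpositionResult, superpose_template, transport_ligands
from .template_pipeline import TemplateEntry

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContactParams:
    """Geometric contact criterion.

    ``sum_of_radii`` (default): dist ≤ r(a) + r(b) + margin — the standard
    physical contact criterion.  ``single_radius``: dist ≤ max(r(a), r(b))
    + margin, for compatibility with single-radius contact definitions.
    """

    margin: float = 0.5
    vdw: VdWTable = DEFAULT_VDW
    radius_mode: str = "sum_of_radii"

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise InputError("contact margin must be >= 0")
        if self.radius_mode not in ("sum_of_radii", "single_radius"):
            raise InputError(f"unknown radius mode: {self.radius_mode}")

    def threshold(self, element_a: str, element_b: str) -> float:
        ra, rb = self.vdw.radius(element_a), self.vdw.radius(element_b)
        if self.radius_mode == "sum_of_radii":
            return ra + rb + self.margin
        return max(ra, rb) + self.margin


@dataclass
class LigandCluster:
    members: list[Ligand]
    cluster_id: int = 0

    @property
    def size(self) -> int:
        return len(self.members)

    def member_ids(self) -> list[str]:
        return [m.instance_id for m in self.members]


@dataclass
class ResidueVote:
    residue: Residue
    contacted: set[str]  # ligand instance ids

    @property
    def votes(self) -> int:
        return len(self.contacted)

    def fraction(self, cluster_size: int) -> float:
        return self.votes / cluster_size


@dataclass
class BindingSitePrediction:
    target_id: str
    predicted_residues: list[Residue]
    cluster: LigandCluster | None
    all_votes: list[ResidueVote]
    params: ContactParams
    min_ligands: int = 2
    min_fraction: float = 0.25
    centroid: Ligand | None = None
    empty_reason: str | None = None

    @property
    def is_empty(self) -> bool:
        return not self.predicted_residues


def atoms_in_contact(a, b, params: ContactParams) -> bool:
    """Van der Waals contact predicate for two (non-hydrogen) atoms."""
    d = float(np.linalg.norm(np.asarray(a.coords) - np.asarray(b.coords)))
    return d <= params.threshold(a.element, b.element)


def _min_gap(coords_a, elems_a, coords_b, elems_b, params: ContactParams) -> float:
    """Smallest (distance - threshold) over all heavy-atom pairs; <=0 means contact."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return np.inf
    d = cdist(coords_a, coords_b)
    ra = np.array([params.vdw.radius(e) for e in elems_a])[:, None]
    rb = np.array([params.vdw.radius(e) for e in elems_b])[None, :]
    if params.radius_mode == "sum_of_radii":
        thr = ra + rb + params.margin
    else:
        thr = np.maximum(ra, rb) + params.margin
    return float((d - thr).min())


def ligand_contact(l1: Ligand, l2: Ligand, params: ContactParams) -> bool:
    """True iff any heavy-atom pair of the two ligands is in contact."""
    return _min_gap(
        l1.heavy_coords(), l1.heavy_elements(),
        l2.heavy_coords(), l2.heavy_elements(), params,
    ) <= 0.0


def cluster_ligands(
    ligands: list[Ligand], params: ContactParams | None = None
) -> list[LigandCluster]:
    """Partition the pooled ligands into continuous masses of contacts.

    Clusters are the connected components of the pairwise contact graph.
    Cluster ids are assigned by decreasing size, then by the smallest
    member instance id, so output order is deterministic.
    """
    params = params or ContactParams()
    if not ligands:
        raise ClusteringError("no relevant ligands in the pool")
    n = len(ligands)
    coords = [lig.heavy_coords() for lig in ligands]
    elems = [lig.heavy_elements() for lig in ligands]
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if _min_gap(coords[i], elems[i], coords[j], elems[j], params) <= 0.0:
                rows += [i, j]
                cols += [j, i]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    groups: dict[int, list[Ligand]] = {}
    for lig, lab in zip(ligands, labels):
        groups.setdefault(int(lab), []).append(lig)
    clusters = [LigandCluster(members=members) for members in groups.values()]
    clusters.sort(key=lambda c: (-c.size, min(c.member_ids())))
    for cid, c in enumerate(clusters):
        c.cluster_id = cid
    return clusters


def tally_votes(
    model: StructureModel, cluster: LigandCluster, params: ContactParams | None = None
) -> list[ResidueVote]:
    """Count, per residue, the distinct cluster ligands it touches.

    Voting is per ligand, not per atom contact: a residue with several
    atoms against the same ligand still gets a single vote from it.
    Residues with no contacts are omitted.
    """
    params = params or ContactParams()
    votes: list[ResidueVote] = []
    for res in model.residues:
        rc = res.heavy_coords()
        re_ = [a.element for a in res.atoms if not a.is_hydrogen]
        contacted = {
            lig.instance_id
            for lig in cluster.members
            if _min_gap(rc, re_, lig.heavy_coords(), lig.heavy_elements(), params) <= 0.0
        }
        if contacted:
            votes.append(ResidueVote(residue=res, contacted=contacted))
    return votes


def select_binding_cluster(
    clusters: list[LigandCluster],
    model: StructureModel | None = None,
    params: ContactParams | None = None,
) -> LigandCluster:
    """Pick the largest cluster as the most likely binding pocket.

    Ties on size are broken by the greater total residue-contact count
    against the model (when a model is supplied), then by the smallest
    member instance id.
    """
    if not clusters:
        raise ClusteringError("no ligand clusters")
    top = max(c.size for c in clusters)
    cands = [c for c in clusters if c.size == top]
    if len(cands) == 1:
        return cands[0]
    if model is not None:
        contact_count = {
            id(c): sum(v.votes for v in tally_votes(model, c, params)) for c in cands
        }
        best = max(contact_count.values())
        cands = [c for c in cands if contact_count[id(c)] == best]
    return min(cands, key=lambda c: min(c.member_ids()))


def centroid_ligand(cluster: LigandCluster) -> Ligand:
    """Member whose geometric centre minimises the summed distance to the
    other members' centres; ties go to the smallest instance id."""
    if not cluster.members:
        raise ClusteringError("empty cluster")
    centers = np.array([m.center() for m in cluster.members])
    dist = cdist(centers, centers).sum(axis=1)
    best = dist.min()
    idx = [i for i, s in enumerate(dist) if np.isclose(s, best, atol=1e-9)]
    return min((cluster.members[i] for i in idx), key=lambda m: m.instance_id)


def _passes_vote(votes: int, cluster_size: int, min_ligands: int, min_fraction: float) -> bool:
    # exact rational comparison: votes/size >= min_fraction with no float error
    frac = Fraction(min_fraction).limit_denominator(10**6)
    return votes >= min_ligands and votes * frac.denominator >= frac.numerator * cluster_size


def apply_voting(
    votes: list[ResidueVote],
    cluster_size: int,
    min_ligands: int = 2,
    min_fraction: float = 0.25,
) -> list[Residue]:
    """Threshold the vote table: keep residues with ≥ min_ligands votes AND
    a vote share ≥ min_fraction of the cluster (both bounds inclusive).

    Output is sorted by (chain, residue number, insertion code).
    """
    if cluster_size < 1:
        raise InputError("cluster size must be >= 1")
    kept = [
        v.residue
        for v in votes
        if _passes_vote(v.votes, cluster_size, min_ligands, min_fraction)
    ]
    kept.sort(key=lambda r: r.key)
    return kept


def predict(
    model: StructureModel,
    templates: list[TemplateEntry],
    params: ContactParams | None = None,
    min_ligands: int = 2,
    min_fraction: float = 0.25,
    tm_threshold: float = 0.4,
    engine: str = "builtin",
    precomputed=None,
) -> tuple[BindingSitePrediction, list[SuperpositionResult]]:
    """End-to-end prediction: superpose each template (gate TM ≥ threshold),
    transport its ligands into the model frame, cluster the pooled ligands,
    select the largest cluster, tally residue votes and apply the voting
    rule.  Runs with zero accepted templates or zero ligands yield an
    explicit empty prediction carrying a machine-readable reason.
    """
    params = params or ContactParams()
    if not model.residues:
        raise InputError("model has no residues")
    if not templates:
        raise InputError("no templates supplied")

    results: list[SuperpositionResult] = []
    pool: list[Ligand] = []
    for tpl in templates:
        res = superpose_template(
            model, tpl, engine=engine, tm_threshold=tm_threshold,
            precomputed=precomputed,
        )
        results.append(res)
        if res.accepted:
            pool.extend(transport_ligands(tpl.ligands, res.transform))

    def empty(reason: str) -> BindingSitePrediction:
        log.warning("empty prediction for %s: %s", model.target_id, reason)
        return BindingSitePrediction(
            target_id=model.target_id, predicted_residues=[], cluster=None,
            all_votes=[], params=params, min_ligands=min_ligands,
            min_fraction=min_fraction, empty_reason=reason,
        )

    if not any(r.accepted for r in results):
        return empty("no accepted superpositions"), results
    if not pool:
        return empty("no relevant ligands"), results

    clusters = cluster_ligands(pool, params)
    cluster = select_binding_cluster(clusters, model, params)
    votes = tally_votes(model, cluster, params)
    predicted = apply_voting(votes, cluster.size, min_ligands, min_fraction)
    prediction = BindingSitePrediction(
        target_id=model.target_id,
        predicted_residues=predicted,
        cluster=cluster,
        all_votes=votes,
        params=params,
        min_ligands=min_ligands,
        min_fraction=min_fraction,
        centroid=centroid_ligand(cluster),
    )
    return prediction, results


# ---------------------------------------------------------------------------
# Output formats


def write_fn_prediction(
    prediction: BindingSitePrediction, path: str | Path,
    author: str = "pocketvote", method: str = "superposition+voting",
) -> None:
    """Write a CASP-FN-style prediction file.

    Dialect: header lines PFRMAT FN / TARGET / AUTHOR / METHOD / MODEL 1,
    one line of space-separated ``<THREE-LETTER><seq_num>`` residue tokens,
    then END.  An empty prediction writes the reason as a comment token.
    """
    lines = [
        "PFRMAT FN",
        f"TARGET {prediction.target_id}",
        f"AUTHOR {author}",
        f"METHOD {method}",
        "MODEL 1",
    ]
    if prediction.predicted_residues:
        lines.append(" ".join(r.token() for r in prediction.predicted_residues))
    else:
        lines.append(f"REMARK NO_PREDICTION {prediction.empty_reason or ''}".rstrip())
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_diagnostics(
    prediction: BindingSitePrediction, tsv_path: str | Path, json_path: str | Path
) -> None:
    """Per-residue vote table (TSV) and cluster summary (JSON)."""
    import pandas as pd

    size = prediction.cluster.size if prediction.cluster else 0
    predicted_ids = {id(r) for r in prediction.predicted_residues}
    rows = []
    for v in sorted(prediction.all_votes, key=lambda v: v.residue.key):
        included = id(v.residue) in predicted_ids
        rows.append({
            "residue": v.residue.token(),
            "chain": v.residue.chain_id,
            "votes": v.votes,
            "cluster_size": size,
            "fraction": round(v.fraction(size), 6) if size else 0.0,
            "included": "Y" if included else "N",
        })
    pd.DataFrame(
        rows, columns=["residue", "chain", "votes", "cluster_size", "fraction", "included"]
    ).to_csv(tsv_path, sep="\t", index=False)

    summary: dict = {"target": prediction.target_id, "empty_reason": prediction.empty_reason}
    if prediction.cluster:
        by_code: dict[str, int] = {}
        provenance: dict[str, int] = {}
        for m in prediction.cluster.members:
            by_code[m.het_code] = by_code.get(m.het_code, 0) + 1
            provenance[m.source_template] = provenance.get(m.source_template, 0) + 1
        summary.update({
            "cluster_size": size,
            "members_by_het_code": dict(sorted(by_code.items())),
            "centroid_ligand": prediction.centroid.het_code if prediction.centroid else None,
            "per_template_ligand_counts": dict(sorted(provenance.items())),
        })
    Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")
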