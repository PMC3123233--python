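"""Synthetic structure generators for end-to-end testing without downloads.

Three generators are provided:

* :func:`make_toy_model` — a backbone-only polymer (helix, extended strand
  or seeded random coil) with plausible Cα spacing.
* :func:`make_template` — a rigidly transformed, optionally noisy copy of
  a model carrying ligands placed at controlled contact offsets from
  anchor residues.
* :func:`make_contact_scenario` — a model plus identity-transform
  templates whose pooled ligands realise a *requested* ligand-ligand and
  residue-ligand contact matrix exactly.  Ligand chains are laid out along
  a line with consecutive spacing just inside the contact threshold
  (threshold − 0.3 Å) so linked pairs touch and unlinked pairs stay well
  clear (≥ threshold + ~0.5 Å); a residue is wired to a ligand by giving
  it a pseudo side-chain atom on a perpendicular ray at contact distance.
  Placements deliberately avoid the inclusive contact boundary so
  outcomes are robust to floating-point noise.

Every emitted bundle is verified by re-running the parsing, clustering
and voting machinery on the written files before it is returned; a bundle
that fails its own ground truth raises instead of poisoning tests.

The geometry is intentionally synthetic: backbones are idealised, pseudo
side chains are unphysical rays, and ligands are mostly single atoms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .binding_site import (
    ContactParams, apply_voting, cluster_ligands, select_binding_cluster,
    tally_votes,
)
from .errors import FixtureError, InputError
from .structure_io import (
    Atom, DEFAULT_VDW, Ligand, Residue, StructureModel, parse_pdb,
    write_structure,
)
from .superposition import RigidTransform

# cyclic amino-acid alphabet giving sequence diversity for alignment seeding
_SEQ_CYCLE = ["ALA", "ASP", "GLU", "PHE", "GLY", "HIS", "ILE", "LYS", "LEU",
              "MET", "ASN", "PRO", "GLN", "ARG", "SER", "THR", "VAL", "TRP",
              "TYR", "CYS"]

# element used for a single-atom ligand of a given chemical component code
_HET_ELEMENT = {
    "ZN": "ZN", "MG": "MG", "MN": "MN", "FE": "FE", "FE2": "FE", "CA": "CA",
    "NI": "NI", "CU": "CU", "CO": "CO", "NA": "NA", "K": "K", "CL": "CL",
    "PO4": "P", "SO4": "S",
}


def _het_element(het_code: str) -> str:
    return _HET_ELEMENT.get(het_code.upper(), "C")


def _backbone_atoms(ca: np.ndarray, serial_start: int) -> list[Atom]:
    # fixed offsets; only Cα geometry matters downstream
    n_pos = ca + np.array([-1.20, 0.70, 0.30])
    c_pos = ca + np.array([1.15, 0.85, -0.25])
    o_pos = c_pos + np.array([0.35, 1.15, 0.20])
    return [
        Atom(serial_start, "N", "N", n_pos),
        Atom(serial_start + 1, "CA", "C", ca),
        Atom(serial_start + 2, "C", "C", c_pos),
        Atom(serial_start + 3, "O", "O", o_pos),
    ]


def make_toy_model(
    n_residues: int,
    geometry: str = "helix",
    seed: int = 0,
    target_id: str = "toy",
    residue_names: dict[int, str] | None = None,
) -> StructureModel:
    """Backbone-only polymer with consecutive Cα spacing 3.8 ± 0.1 Å.

    ``geometry`` is one of ``helix`` (ideal α-helix parameters), ``extended``
    (straight strand) or ``random_coil`` (seeded fixed-step random walk).
    ``residue_names`` overrides the cyclic residue naming at 0-based indices.
    Deterministic for a fixed seed.
    """
    if n_residues < 3:
        raise InputError("need at least 3 residues")
    idx = np.arange(n_residues)
    if geometry == "helix":
        # radius 2.3 Å, 100° twist, 1.5 Å rise → Cα-Cα chord ≈ 3.83 Å
        theta = np.deg2rad(100.0) * idx
        ca = np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * idx])
    elif geometry == "extended":
        ca = np.column_stack([3.79 * idx, 0.3 * (-1.0) ** idx, np.zeros(n_residues)])
    elif geometry == "random_coil":
        rng = np.random.default_rng(seed)
        steps = rng.normal(size=(n_residues - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        ca = np.vstack([np.zeros(3), np.cumsum(3.8 * steps, axis=0)])
    else:
        raise InputError(f"unknown geometry: {geometry}")

    residue_names = residue_names or {}
    residues = []
    serial = 1
    for i in range(n_residues):
        name = residue_names.get(i, _SEQ_CYCLE[i % len(_SEQ_CYCLE)])
        residues.append(
            Residue(chain_id="A", seq_num=i + 1, icode=" ", res_name=name,
                    atoms=_backbone_atoms(ca[i], serial))
        )
        serial += 4
    return StructureModel(target_id=target_id, residues=residues)


def _euler_transform(rotation_angles, translation) -> RigidTransform:
    R = Rotation.from_euler("xyz", rotation_angles, degrees=True).as_matrix()
    return RigidTransform(R, np.asarray(translation, dtype=float))


def _place_ligand_atom(
    model: StructureModel, anchor_index: int, het_code: str, offset: float,
    vdw=DEFAULT_VDW,
) -> np.ndarray:
    """Position for a single ligand atom whose nearest heavy-atom distance
    to the anchor residue equals (anchor radius + ligand radius + offset).

    The atom is pushed along the ray from the structure centroid through
    the anchor Cα; the scale is solved by bisection.
    """
    res = model.residues[anchor_index]
    anchor_coords = res.heavy_coords()
    anchor_elems = [a.element for a in res.atoms if not a.is_hydrogen]
    anchor_radii = np.array([vdw.radius(e) for e in anchor_elems])
    r_lig = vdw.radius(_het_element(het_code))
    centroid = np.vstack([r.heavy_coords() for r in model.residues]).mean(axis=0)
    ca = res.ca().coords
    direction = ca - centroid
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])

    def gap(s: float) -> float:
        p = ca + s * direction
        return float(np.min(np.linalg.norm(anchor_coords - p, axis=1) - anchor_radii - r_lig))

    lo, hi = 0.0, 60.0
    if gap(hi) < offset:
        raise FixtureError("cannot place ligand: ray too short")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if gap(mid) < offset:
            lo = mid
        else:
            hi = mid
    return ca + hi * direction


def make_template(
    model: StructureModel,
    rotation_angles=(0.0, 0.0, 0.0),
    translation=(0.0, 0.0, 0.0),
    coord_noise: float = 0.0,
    ligand_placements: list[tuple[str, int, float]] = (),
    seed: int = 0,
    path: str | Path | None = None,
    template_id: str = "templ",
) -> tuple[Path, RigidTransform]:
    """Write a template PDB: a rigid copy of the model (Euler angles in
    degrees + translation) with optional Gaussian coordinate noise on the
    protein and ligands planted at controlled offsets.

    Each ``(het_code, anchor_residue_index, offset)`` placement puts a
    single-atom ligand whose nearest heavy-atom distance to its anchor
    residue, measured in the model frame, is exactly the sum of the two
    van der Waals radii plus ``offset`` (so offset ≤ 0.5 ⇒ contact under
    the default margin, offset > 0.5 ⇒ no contact).  Returns the file path
    and the applied transform.  The written file is verified by re-parsing.
    """
    if coord_noise < 0:
        raise InputError("coord_noise must be >= 0")
    transform = _euler_transform(rotation_angles, translation)
    rng = np.random.default_rng(seed)

    residues = []
    serial = 1
    for res in model.residues:
        atoms = []
        for a in res.atoms:
            pos = transform.apply(a.coords)
            if coord_noise > 0:
                pos = pos + rng.normal(scale=coord_noise, size=3)
            atoms.append(Atom(serial, a.name, a.element, pos, is_hydrogen=a.is_hydrogen))
            serial += 1
        residues.append(Residue(res.chain_id, res.seq_num, res.icode, res.res_name, atoms))
    templ_model = StructureModel(target_id=template_id, residues=residues)

    ligands = []
    for k, (het_code, anchor_idx, offset) in enumerate(ligand_placements):
        pos_model_frame = _place_ligand_atom(model, anchor_idx, het_code, offset)
        atom = Atom(serial, _het_element(het_code), _het_element(het_code),
                    transform.apply(pos_model_frame), is_hetero=True)
        serial += 1
        ligands.append(Ligand(het_code=het_code.upper(), atoms=[atom],
                              source_template=template_id,
                              instance_id=f"{template_id}/{k}:{het_code.upper()}"))

    if path is None:
        raise InputError("make_template needs an output path")
    path = Path(path)
    write_structure(templ_model, ligands, path)
    reparsed_model, reparsed_ligands = parse_pdb(path, target_id=template_id)
    if len(reparsed_model) != len(model) or len(reparsed_ligands) != len(ligands):
        raise FixtureError(f"template round-trip failed for {path}")
    return path, transform


# ---------------------------------------------------------------------------
# Contact scenarios


@dataclass
class ContactSpec:
    """A requested contact matrix.

    ``ligands`` maps label → chemical component code.  ``chain_links`` are
    ligand label pairs that must touch; within each connected group the
    links must form a simple path (laid out along a line).  Each
    ``residue_targets`` entry wires one residue (0-based model index) to a
    set of ligand labels it must contact — and no others.
    """

    ligands: dict[str, str]
    chain_links: list[tuple[str, str]] = field(default_factory=list)
    residue_targets: dict[int, list[str]] = field(default_factory=dict)
    n_residues: int = 60
    residue_names: dict[int, str] = field(default_factory=dict)
    seed: int = 0
    n_templates: int = 1


@dataclass
class FixtureBundle:
    model_path: Path
    template_paths: list[Path]
    ground_truth: dict
    manifest_path: Path | None = None


def _link_components(labels: list[str], links: list[tuple[str, str]]) -> list[list[str]]:
    """Connected components of the link graph as label paths (line order).

    Each component must be a simple path: every node degree ≤ 2, no cycles.
    Isolated labels become singleton components.
    """
    adj: dict[str, list[str]] = {lab: [] for lab in labels}
    for a, b in links:
        if a not in adj or b not in adj:
            raise InputError(f"link references unknown ligand label: {a}, {b}")
        adj[a].append(b)
        adj[b].append(a)
    if any(len(v) > 2 for v in adj.values()):
        raise FixtureError("link graph must be a union of simple paths (degree ≤ 2)")
    seen: set[str] = set()
    components: list[list[str]] = []
    for lab in labels:
        if lab in seen:
            continue
        # walk to one end of the path, then traverse
        end = lab
        prev = None
        while True:
            nxt = [x for x in adj[end] if x != prev]
            if not nxt:
                break
            prev, end = end, nxt[0]
            if end == lab:  # cycle
                raise FixtureError("link graph contains a cycle; paths only")
        path = [end]
        seen.add(end)
        while True:
            nxt = [x for x in adj[path[-1]] if x not in seen]
            if not nxt:
                break
            path.append(nxt[0])
            seen.add(nxt[0])
        components.append(path)
    return components


def make_contact_scenario(
    spec: ContactSpec, out_dir: str | Path, params: ContactParams | None = None
) -> FixtureBundle:
    """Emit a model + identity templates realising the requested contacts.

    The written bundle is self-verified: the files are re-parsed, the
    pooled ligands clustered and the votes tallied, and the result must
    equal the spec-derived ground truth exactly.
    """
    params = params or ContactParams()
    vdw = params.vdw
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = list(spec.ligands)
    if not labels:
        raise InputError("scenario needs at least one ligand")
    for idx in spec.residue_targets:
        if not 0 <= idx < spec.n_residues:
            raise InputError(f"residue index {idx} outside model")

    model = make_toy_model(
        spec.n_residues, geometry="helix", seed=spec.seed,
        target_id="scenario", residue_names=spec.residue_names,
    )

    # lay each link-path along x, one line per component, far from the protein
    components = _link_components(labels, spec.chain_links)
    positions: dict[str, np.ndarray] = {}
    for comp_idx, comp in enumerate(components):
        y0 = 500.0 + 120.0 * comp_idx
        x = 0.0
        prev_elem = None
        for lab in comp:
            elem = _het_element(spec.ligands[lab])
            if prev_elem is not None:
                thr = params.threshold(prev_elem, elem)
                x += thr - 0.3  # safely inside the inclusive boundary
            positions[lab] = np.array([x, y0, 0.0])
            prev_elem = elem

    # pseudo side-chain atoms: one per (residue, targeted ligand), on a
    # perpendicular ray at contact distance (threshold − 0.3)
    contact_elem = "C"
    target_items = sorted(spec.residue_targets.items())
    for rank, (res_idx, lig_labels) in enumerate(target_items):
        phi = 2.0 * np.pi * rank / max(len(target_items), 1)
        ray = np.array([0.0, np.cos(phi), np.sin(phi)])
        res = model.residues[res_idx]
        for j, lab in enumerate(lig_labels):
            if lab not in positions:
                raise InputError(f"residue {res_idx} targets unknown ligand {lab}")
            elem = _het_element(spec.ligands[lab])
            d = params.threshold(contact_elem, elem) - 0.3
            pos = positions[lab] + d * ray
            res.atoms.append(
                Atom(serial=9000 + 100 * rank + j, name=f"X{j+1}",
                     element=contact_elem, coords=pos)
            )

    model_path = out_dir / f"{model.target_id}.pdb"  # stem doubles as target id
    write_structure(model, [], model_path)

    # identity templates carrying the ligands, round-robin
    ligand_objs: list[list[Ligand]] = [[] for _ in range(max(spec.n_templates, 1))]
    for k, lab in enumerate(labels):
        het = spec.ligands[lab].upper()
        elem = _het_element(het)
        atom = Atom(serial=1, name=elem, element=elem, coords=positions[lab],
                    is_hetero=True)
        ligand_objs[k % len(ligand_objs)].append(
            Ligand(het_code=het, atoms=[atom], instance_id=lab)
        )
    template_paths = []
    for t_idx, ligs in enumerate(ligand_objs):
        tpath = out_dir / f"template_{t_idx}.pdb"
        write_structure(model, ligs, tpath)
        template_paths.append(tpath)

    ground_truth = _derive_ground_truth(spec, components, model)
    bundle = FixtureBundle(model_path=model_path, template_paths=template_paths,
                           ground_truth=ground_truth)
    _verify_bundle(bundle, params)
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({
        "seed": spec.seed,
        "model": model_path.name,
        "templates": [p.name for p in template_paths],
        "ground_truth": ground_truth,
    }, indent=2) + "\n")
    bundle.manifest_path = manifest
    return bundle


def _derive_ground_truth(spec: ContactSpec, components, model) -> dict:
    sizes = sorted((len(c) for c in components), reverse=True)
    if sizes.count(sizes[0]) > 1:
        raise FixtureError("ambiguous largest cluster; make one component biggest")
    largest = max(components, key=len)
    largest_set = set(largest)
    votes = {}
    for res_idx, labs in sorted(spec.residue_targets.items()):
        n = len(set(labs) & largest_set)
        if n:
            votes[model.residues[res_idx].token()] = n
    cluster_size = len(largest)
    predicted = sorted(
        (tok for tok, v in votes.items() if v >= 2 and 4 * v >= cluster_size),
        key=lambda tok: int("".join(c for c in tok if c.isdigit())),
    )
    return {
        "cluster_sizes": sizes,
        "largest_cluster_size": cluster_size,
        "votes": votes,
        "fractions": {tok: v / cluster_size for tok, v in votes.items()},
        "predicted_residues": predicted,
    }


def _verify_bundle(bundle: FixtureBundle, params: ContactParams) -> None:
    """Closed loop: parse the emitted files and re-derive the ground truth."""
    model, _ = parse_pdb(bundle.model_path)
    pool = []
    for tpath in bundle.template_paths:
        _, ligs = parse_pdb(tpath)
        pool.extend(ligs)
    clusters = cluster_ligands(pool, params)
    gt = bundle.ground_truth
    sizes = sorted((c.size for c in clusters), reverse=True)
    if sizes != gt["cluster_sizes"]:
        raise FixtureError(f"cluster sizes {sizes} != expected {gt['cluster_sizes']}")
    best = select_binding_cluster(clusters, model, params)
    votes = tally_votes(model, best, params)
    realised = {v.residue.token(): v.votes for v in votes}
    if realised != gt["votes"]:
        raise FixtureError(f"votes {realised} != expected {gt['votes']}")
    predicted = [r.token() for r in apply_voting(votes, best.size)]
    if sorted(predicted) != sorted(gt["predicted_residues"]):
        raise FixtureError(f"prediction {predicted} != expected {gt['predicted_residues']}")


def figure1(out_dir: str | Path, seed: int = 0) -> FixtureBundle:
    """Canonical worked example: a single continuous mass of 13 ligands
    (1 ZN, 6 FE, 1 NI, 1 MG, 1 GDP, 3 PO4) wired so the four true binding
    residues receive 7, 11, 12 and 5 votes (53.85%, 84.62%, 92.31%,
    38.46% of the cluster) and two decoy residues receive 2 and 1 votes
    (15.38%, 7.69%), which the 2-ligand/25% rule excludes.
    """
    ligands = {"ZN": "ZN", "FE1": "FE", "FE2": "FE", "FE3": "FE", "FE4": "FE",
               "FE5": "FE", "FE6": "FE", "NI": "NI", "MG": "MG", "GDP": "GDP",
               "PO4A": "PO4", "PO4B": "PO4", "PO4C": "PO4"}
    order = list(ligands)
    links = list(zip(order, order[1:]))  # one continuous mass
    spec = ContactSpec(
        ligands=ligands,
        chain_links=links,
        residue_targets={
            28: ["ZN", "FE1", "FE2", "FE3", "FE4", "FE5", "FE6"],          # 7/13
            57: ["ZN", "FE1", "FE2", "FE3", "FE4", "FE5", "FE6", "NI",
                 "MG", "PO4A", "PO4B"],                                     # 11/13
            58: ["ZN", "FE1", "FE2", "FE3", "FE4", "FE5", "FE6", "NI",
                 "MG", "PO4A", "PO4B", "PO4C"],                             # 12/13
            121: ["FE2", "FE3", "FE4", "NI", "MG"],                         # 5/13
            89: ["GDP", "PO4A"],                                            # 2/13 decoy
            99: ["GDP"],                                                    # 1/13 decoy
        },
        n_residues=130,
        residue_names={28: "HIS", 57: "HIS", 58: "ASP", 121: "ASP",
                       89: "SER", 99: "GLY"},
        seed=seed,
    )
    return make_contact_scenario(spec, out_dir)


def make_planted_bundle(
    out_dir: str | Path,
    n_templates: int = 5,
    n_residues: int = 30,
    anchor: int = 14,
    seed: int = 0,
) -> FixtureBundle:
    """Planted-pocket bundle: every template is a rigid (noise-free) copy
    of the model carrying one ZN at the same model-frame pocket, so the
    ground-truth binding residues are exactly those within contact
    distance of the planted site.
    """
    if n_templates < 2:
        raise InputError("need >= 2 templates so the voting minimum can be met")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    model = make_toy_model(n_residues, geometry="helix", seed=seed, target_id="planted")
    model_path = out_dir / f"{model.target_id}.pdb"
    write_structure(model, [], model_path)

    zn_pos = _place_ligand_atom(model, anchor, "ZN", offset=-0.3)
    params = ContactParams()
    truth = []
    for res in model.residues:
        coords = res.heavy_coords()
        elems = [a.element for a in res.atoms if not a.is_hydrogen]
        thr = np.array([params.threshold(e, "ZN") for e in elems])
        if np.any(np.linalg.norm(coords - zn_pos, axis=1) <= thr):
            truth.append(res.token())

    template_paths = []
    for t in range(n_templates):
        angles = rng.uniform(-180, 180, size=3)
        shift = rng.uniform(-30, 30, size=3)
        tpath, _ = make_template(
            model, rotation_angles=angles, translation=shift, coord_noise=0.0,
            ligand_placements=[("ZN", anchor, -0.3)],
            seed=seed + t, path=out_dir / f"template_{t}.pdb",
            template_id=f"templ{t}",
        )
        template_paths.append(tpath)

    return FixtureBundle(
        model_path=model_path,
        template_paths=template_paths,
        ground_truth={"predicted_residues": sorted(truth),
                      "largest_cluster_size": n_templates},
    )
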