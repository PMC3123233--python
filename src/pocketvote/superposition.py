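"""Rigid-body superposition of templates onto a model, TM-score gating,
and transport of template ligands into the model coordinate frame.

The built-in engine seeds a residue pairing from the global sequence
alignment and iterates least-squares (Kabsch) superposition on the Cα
pairs, discarding pairs beyond a distance cutoff that anneals from 8 Å
down to 4 Å, until the included pair set is stable.  The resulting
transform is scored with the standard TM-score,

    TM = (1/L) Σ_pairs 1 / (1 + (d_i/d0)^2),
    d0(L) = max(0.5, 1.24 (L - 15)^(1/3) - 1.8),

normalised by the model (target) length L.  A superposition is accepted
only when TM ≥ 0.4 — the conventional threshold above which two chains
share a significantly related fold — and only accepted templates are
allowed to contribute ligands downstream.

Alternative engines: ``external`` drives a TM-align-compatible executable
and parses its ``-m`` rotation-matrix file; ``precomputed`` reads
transforms from a plain-text file.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import AlignmentError, EnvironmentError_, InputError
from .structure_io import Ligand, StructureModel, write_structure
from .template_pipeline import TemplateEntry, global_alignment_pairs

log = logging.getLogger(__name__)

TM_THRESHOLD_DEFAULT = 0.4


@dataclass(frozen=True)
class RigidTransform:
    """x ↦ R x + t with R a proper rotation."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise InputError("rigid transform needs a 3x3 rotation and 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise InputError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise InputError("rotation matrix must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: first apply ``other``, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class SuperpositionResult:
    template_id: str
    transform: RigidTransform
    tm_score: float
    n_aligned: int
    aligned_pairs: list[tuple[int, int]]
    engine: str  # builtin | external | precomputed
    accepted: bool
    rmsd: float = float("nan")


def kabsch(
    model_points: np.ndarray, template_points: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of template points onto model points.

    Returns the transform minimising the RMSD of the transformed template
    points against the model points, with a proper rotation enforced
    (reflections corrected), and that minimal RMSD in Å.
    """
    P = np.asarray(model_points, dtype=float)
    Q = np.asarray(template_points, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise AlignmentError("point lists must be equal-length lists of 3-vectors")
    n = P.shape[0]
    if n < 3:
        raise AlignmentError("need at least 3 point pairs for superposition")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    if np.linalg.matrix_rank(np.vstack([Pc, Qc]), tol=1e-9) < 2:
        raise AlignmentError("degenerate (collinear or coincident) point geometry")
    # scipy's align_vectors implements Kabsch with the reflection correction
    rot, rssd = Rotation.align_vectors(Pc, Qc)
    R = rot.as_matrix()
    t = cp - R @ cq
    transform = RigidTransform(R, t)
    rmsd = float(rssd) / np.sqrt(n)
    return transform, rmsd


def tm_d0(l_target: int) -> float:
    """Distance scale d0 of the TM-score, floored at 0.5 Å for short chains."""
    if l_target < 1:
        raise InputError("target length must be >= 1")
    return max(0.5, 1.24 * np.cbrt(max(l_target - 15, 0)) - 1.8)


def tm_score(
    model_ca: np.ndarray,
    template_ca_transformed: np.ndarray,
    aligned_pairs: list[tuple[int, int]],
    l_target: int,
) -> float:
    """Length-normalised structural similarity in [0, 1]."""
    if not aligned_pairs:
        return 0.0
    d0 = tm_d0(l_target)
    mi = np.array([p[0] for p in aligned_pairs])
    ti = np.array([p[1] for p in aligned_pairs])
    d = np.linalg.norm(
        np.asarray(model_ca)[mi] - np.asarray(template_ca_transformed)[ti], axis=1
    )
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_target)


# annealing schedule for the pair-inclusion cutoff, Å
_CUTOFF_SCHEDULE = (8.0, 7.0, 6.0, 5.0, 4.0)
_MAX_ITER = 50


def _iterative_superposition(
    model_ca: np.ndarray, template_ca: np.ndarray, seed_pairs: list[tuple[int, int]]
) -> tuple[RigidTransform, float]:
    """Sequence-seeded iterative Kabsch with an annealed distance cutoff."""
    pairs = np.array(seed_pairs, dtype=int)
    if len(pairs) < 3:
        raise AlignmentError("fewer than 3 aligned residue pairs")
    included = np.ones(len(pairs), dtype=bool)
    transform, rmsd = kabsch(model_ca[pairs[:, 0]], template_ca[pairs[:, 1]])
    schedule = list(_CUTOFF_SCHEDULE) + [_CUTOFF_SCHEDULE[-1]] * _MAX_ITER
    for cutoff in schedule[:_MAX_ITER]:
        moved = transform.apply(template_ca[pairs[:, 1]])
        d = np.linalg.norm(model_ca[pairs[:, 0]] - moved, axis=1)
        new_included = d <= cutoff
        if new_included.sum() < 3:
            break  # keep the previous transform rather than degenerate fits
        if cutoff == _CUTOFF_SCHEDULE[-1] and np.array_equal(new_included, included):
            break
        included = new_included
        sub = pairs[included]
        try:
            transform, rmsd = kabsch(model_ca[sub[:, 0]], template_ca[sub[:, 1]])
        except AlignmentError:
            break
    return transform, rmsd


def _parse_matrix_file(path: Path) -> RigidTransform:
    """Parse a TM-align ``-m`` rotation file: 3 rows of (i, t_i, u_i1..u_i3)."""
    rows = []
    for line in path.read_text().splitlines():
        parts = line.split()
        if len(parts) == 5 and parts[0] in {"0", "1", "2", "3"}:
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError:
                continue
        if len(rows) == 3:
            break
    if len(rows) != 3:
        raise EnvironmentError_(f"could not parse rotation matrix from {path}")
    arr = np.array(rows)
    return RigidTransform(rotation=arr[:, 1:4], translation=arr[:, 0])


def read_transform_file(path: str | Path) -> dict[str, RigidTransform]:
    """Read precomputed transforms: 12 numbers per line (row-major rotation
    then translation), with an optional ``# template_id`` trailing comment.
    Lines without an id are keyed by position (``"0"``, ``"1"``, ...).
    """
    transforms: dict[str, RigidTransform] = {}
    for idx, raw in enumerate(Path(path).read_text().splitlines()):
        line, _, comment = raw.partition("#")
        line = line.strip()
        if not line:
            continue
        nums = [float(x) for x in line.split()]
        if len(nums) != 12:
            raise InputError(f"transform line needs 12 numbers, got {len(nums)}")
        key = comment.strip() or str(len(transforms))
        transforms[key] = RigidTransform(
            rotation=np.array(nums[:9]).reshape(3, 3),
            translation=np.array(nums[9:]),
        )
    return transforms


def _run_external_aligner(
    model: StructureModel, template: TemplateEntry, command: str
) -> tuple[RigidTransform, float]:
    """Run a TM-align-compatible binary and parse the transform + TM-score.

    ``command`` is the executable name/path; it is invoked as
    ``cmd template.pdb model.pdb -m matrix.txt`` so the reported transform
    maps the template onto the model.
    """
    exe = shutil.which(command)
    if exe is None:
        raise EnvironmentError_(f"external aligner not found: {command}")
    with tempfile.TemporaryDirectory() as tmp:
        tdir = Path(tmp)
        mpath, tpath, mat = tdir / "model.pdb", tdir / "templ.pdb", tdir / "matrix.txt"
        write_structure(model, [], mpath)
        write_structure(template.structure, [], tpath)
        proc = subprocess.run(
            [exe, str(tpath), str(mpath), "-m", str(mat)],
            capture_output=True, text=True,
        )
        if proc.returncode != 0:
            raise EnvironmentError_(
                f"external aligner failed ({command}): {proc.stderr.strip()[:200]}"
            )
        tm = None
        for line in proc.stdout.splitlines():
            if line.startswith("TM-score=") and "Chain_2" in line:
                tm = float(line.split("=")[1].split()[0])
        if tm is None:  # fall back to the first TM-score line
            for line in proc.stdout.splitlines():
                if line.startswith("TM-score="):
                    tm = float(line.split("=")[1].split()[0])
                    break
        if tm is None:
            raise EnvironmentError_(f"no TM-score in output of {command}")
        return _parse_matrix_file(mat), tm


def superpose_template(
    model: StructureModel,
    template: TemplateEntry,
    engine: str = "builtin",
    tm_threshold: float = TM_THRESHOLD_DEFAULT,
    external_command: str = "TMalign",
    precomputed: dict[str, RigidTransform] | None = None,
) -> SuperpositionResult:
    """Superpose one template onto the model and gate on the TM-score.

    Returns a :class:`SuperpositionResult` whose ``accepted`` flag is True
    iff the TM-score (normalised by the model length) reaches
    ``tm_threshold``.  Rejected results still carry the score so the
    rejection is auditable.
    """
    model_res = model.residues_with_ca()
    templ_res = template.structure.residues_with_ca()
    if len(model_res) < 3 or len(templ_res) < 3:
        raise AlignmentError("both structures need >= 3 residues with a Cα atom")
    model_ca = np.array([r.ca().coords for r in model_res])
    templ_ca = np.array([r.ca().coords for r in templ_res])
    model_seq = "".join(r.one_letter for r in model_res)
    templ_seq = "".join(r.one_letter for r in templ_res)
    pairs = global_alignment_pairs(model_seq, templ_seq)
    l_target = len(model_res)

    rmsd = float("nan")
    if engine == "builtin":
        transform, rmsd = _iterative_superposition(model_ca, templ_ca, pairs)
    elif engine == "external":
        transform, _ = _run_external_aligner(model, template, external_command)
    elif engine == "precomputed":
        if precomputed is None or template.template_id not in precomputed:
            raise InputError(f"no precomputed transform for {template.template_id}")
        transform = precomputed[template.template_id]
    else:
        raise InputError(f"unknown superposition engine: {engine}")

    score = tm_score(model_ca, transform.apply(templ_ca), pairs, l_target)
    accepted = score >= tm_threshold
    if not accepted:
        log.info(
            "template %s rejected: TM-score %.3f < %.2f",
            template.template_id, score, tm_threshold,
        )
    return SuperpositionResult(
        template_id=template.template_id,
        transform=transform,
        tm_score=score,
        n_aligned=len(pairs),
        aligned_pairs=pairs,
        engine=engine,
        accepted=accepted,
        rmsd=rmsd,
    )


def transport_ligands(
    ligands: list[Ligand], transform: RigidTransform
) -> list[Ligand]:
    """Map ligand atom coordinates into the model frame (x ↦ R x + t).

    Chemical codes and instance ids are preserved; the map is an isometry,
    so intra-ligand geometry is unchanged.
    """
    return [lig.transformed(transform.apply) for lig in ligands]
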