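"""Binding-site assessment: MCC, BDT, per-target Z-scores and paired
group comparisons.

MCC treats binding-residue prediction as a binary classification over the
target sequence; optionally, "neutral" residues (annotated as capable of
binding an alternative ligand but not observed binding) are removed from
both sets and from the universe before counting.

BDT rewards spatial proximity rather than exact identity: each predicted
residue contributes 1/(1 + (D_i/d0)^2), where D_i is its minimum
heavy-atom distance to any observed binding residue in the native
structure, and the sum is normalised by max(|predicted|, |observed|), so
both over- and under-prediction are penalised.  The distance constant
defaults to d0 = 1 Å.

Cross-target normalisation uses per-target Z-scores over the groups that
predicted that target (sample standard deviation); method pairs are
compared on their common target subset with a two-sided Wilcoxon
signed-rank test (exact null distribution for small n after dropping zero
differences, normal approximation with continuity correction otherwise).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import wilcoxon

from .errors import EvaluationError, InputError

log = logging.getLogger(__name__)


@dataclass
class BindingSiteAnnotation:
    target_id: str
    observed_residues: set[str]
    neutral_residues: set[str] = field(default_factory=set)
    # residue token -> (n_atoms, 3) heavy-atom coordinates in the native frame
    native_coords: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.observed_residues & self.neutral_residues:
            raise InputError("observed and neutral residue sets overlap")


@dataclass
class ScoreRecord:
    group_id: str
    target_id: str
    mcc: float
    bdt: float


@dataclass
class ComparisonSummary:
    group_a: str
    group_b: str
    n_common: int
    mean_a: dict[str, float]
    mean_b: dict[str, float]
    p_value: dict[str, float]
    z_mean_a: dict[str, float] = field(default_factory=dict)
    z_mean_b: dict[str, float] = field(default_factory=dict)
    below_min_common: bool = False


def mcc(
    predicted: set[str],
    annotation: BindingSiteAnnotation,
    n_residues: int,
    exclude_neutral: bool = True,
) -> float:
    """Matthews correlation of predicted vs observed binding residues.

    The universe is the ``n_residues`` positions of the target sequence;
    with ``exclude_neutral`` the neutral residues are removed from both
    sets and from the universe.  Degenerate confusion tables (any zero
    factor under the square root) score 0 by convention.
    """
    if n_residues <= 0:
        raise InputError("n_residues must be positive")
    observed = set(annotation.observed_residues)
    pred = set(predicted)
    universe_n = n_residues
    if exclude_neutral:
        neutral = annotation.neutral_residues
        universe_n -= len(neutral)
        observed -= neutral
        pred -= neutral
    tp = len(pred & observed)
    fp = len(pred - observed)
    fn = len(observed - pred)
    tn = universe_n - tp - fp - fn
    if tn < 0:
        raise InputError("n_residues smaller than |predicted ∪ observed|")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def bdt(
    predicted: set[str],
    annotation: BindingSiteAnnotation,
    d0: float = 1.0,
) -> float:
    """Binding-site distance test score in [0, 1].

    D_i is the minimum heavy-atom distance from predicted residue i to any
    observed residue, measured on the native coordinates; a predicted
    residue with no native coordinates contributes zero (with a warning).
    """
    if d0 <= 0:
        raise InputError("d0 must be positive")
    observed = annotation.observed_residues
    if not observed:
        raise EvaluationError(f"{annotation.target_id}: no observed residues")
    if not predicted:
        return 0.0
    obs_coords = [
        annotation.native_coords[r] for r in sorted(observed)
        if r in annotation.native_coords
    ]
    if not obs_coords:
        raise EvaluationError(
            f"{annotation.target_id}: no native coordinates for observed residues"
        )
    obs_all = np.vstack(obs_coords)
    total = 0.0
    for r in predicted:
        coords = annotation.native_coords.get(r)
        if coords is None or len(coords) == 0:
            log.warning("%s: predicted residue %s missing from native structure",
                        annotation.target_id, r)
            continue
        d_min = float(cdist(np.atleast_2d(coords), obs_all).min())
        total += 1.0 / (1.0 + (d_min / d0) ** 2)
    return total / max(len(predicted), len(observed))


def zscores(
    score_matrix: dict[tuple[str, str], float]
) -> dict[tuple[str, str], float]:
    """Per-target Z-scores over the groups that scored each target.

    Sample (n−1) standard deviation; a target where all groups scored
    identically gets z = 0 for everyone; targets with fewer than two
    scores are excluded with a warning.  Negative z-scores are kept.
    """
    by_target: dict[str, list[tuple[str, float]]] = {}
    for (group, target), score in score_matrix.items():
        by_target.setdefault(target, []).append((group, score))
    out: dict[tuple[str, str], float] = {}
    for target, pairs in by_target.items():
        if len(pairs) < 2:
            log.warning("target %s scored by <2 groups; excluded from Z-scores", target)
            continue
        values = np.array([s for _, s in pairs], dtype=float)
        sd = values.std(ddof=1)
        mean = values.mean()
        # guard against pure rounding noise masquerading as spread
        degenerate = sd <= 1e-12 * max(1.0, abs(mean))
        for (group, score) in pairs:
            out[(group, target)] = 0.0 if degenerate else (score - mean) / sd
    return out


def wilcoxon_signed_rank(
    a: np.ndarray, b: np.ndarray, exact_max_n: int = 25
) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (standard signed-rank convention); the
    exact null distribution is used for n ≤ ``exact_max_n`` remaining
    pairs, the normal approximation with continuity correction above.
    All-zero differences return p = 1 (no evidence of a difference).
    """
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    diff = diff[diff != 0]
    n = len(diff)
    if n == 0:
        return 1.0
    method = "exact" if n <= exact_max_n else "approx"
    res = wilcoxon(diff, alternative="two-sided", method=method, correction=True)
    return float(min(res.pvalue, 1.0))


def compare_groups(
    a: list[ScoreRecord],
    b: list[ScoreRecord],
    min_common: int = 15,
    zscore_matrices: dict[str, dict[tuple[str, str], float]] | None = None,
) -> ComparisonSummary:
    """Paired comparison of two groups on their common target subset.

    Means, mean Z-scores (when a Z-score matrix over all groups is
    supplied) and two-sided Wilcoxon p-values are computed per metric over
    exactly the targets both groups predicted.  Comparisons with fewer
    than ``min_common`` shared targets are flagged, mirroring the usual
    minimum-prediction cutoff in benchmark figures.
    """
    if not a or not b:
        raise EvaluationError("both groups need at least one score record")
    ga, gb = a[0].group_id, b[0].group_id
    rec_a = {r.target_id: r for r in a}
    rec_b = {r.target_id: r for r in b}
    common = sorted(set(rec_a) & set(rec_b))
    if not common:
        raise EvaluationError(f"no common targets between {ga} and {gb}")

    mean_a: dict[str, float] = {}
    mean_b: dict[str, float] = {}
    p_value: dict[str, float] = {}
    for metric in ("mcc", "bdt"):
        va = np.array([getattr(rec_a[t], metric) for t in common])
        vb = np.array([getattr(rec_b[t], metric) for t in common])
        mean_a[metric] = float(va.mean())
        mean_b[metric] = float(vb.mean())
        p_value[metric] = wilcoxon_signed_rank(va, vb)

    summary = ComparisonSummary(
        group_a=ga, group_b=gb, n_common=len(common),
        mean_a=mean_a, mean_b=mean_b, p_value=p_value,
        below_min_common=len(common) < min_common,
    )
    if zscore_matrices is not None:
        for metric, matrix in zscore_matrices.items():
            za = [matrix[(ga, t)] for t in common if (ga, t) in matrix]
            zb = [matrix[(gb, t)] for t in common if (gb, t) in matrix]
            if za:
                summary.z_mean_a[metric] = float(np.mean(za))
            if zb:
                summary.z_mean_b[metric] = float(np.mean(zb))
    return summary


# ---------------------------------------------------------------------------
# Annotation / prediction file parsing


def parse_fn_prediction(path: str | Path, strict: bool = False) -> tuple[str, set[str]]:
    """Parse a CASP-FN-style prediction file into (target_id, residue tokens).

    In loose mode (default) unknown header lines are ignored and residue
    tokens may be split across multiple lines; strict mode requires the
    PFRMAT FN header and a MODEL/END bracket.
    """
    path = Path(path)
    target = path.stem
    tokens: set[str] = set()
    saw_pfrmat = saw_model = saw_end = False
    in_model = not strict
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        keyword = line.split()[0].upper()
        if keyword == "PFRMAT":
            saw_pfrmat = True
            if strict and "FN" not in line.upper():
                raise InputError(f"{path}:{lineno}: not an FN-format file")
        elif keyword == "TARGET":
            parts = line.split()
            if len(parts) > 1:
                target = parts[1]
        elif keyword in ("AUTHOR", "METHOD", "REMARK", "SCORE", "PARENT"):
            continue
        elif keyword == "MODEL":
            saw_model = in_model = True
        elif keyword == "END" or keyword == "TER":
            saw_end = True
            in_model = not strict
        elif in_model:
            for token in line.split():
                token = token.upper().rstrip(",;")
                if not any(c.isdigit() for c in token):
                    if strict:
                        raise InputError(f"{path}:{lineno}: bad residue token {token!r}")
                    continue
                tokens.add(token)
        elif strict:
            raise InputError(f"{path}:{lineno}: unexpected line outside MODEL block")
    if strict and not (saw_pfrmat and saw_model and saw_end):
        raise InputError(f"{path}: incomplete FN file (PFRMAT/MODEL/END required)")
    return target, tokens


def residue_number(token: str) -> int:
    """Numeric part of a residue token: 'HIS29' → 29, '112' → 112."""
    digits = "".join(c for c in token if c.isdigit() or c == "-")
    if not digits:
        raise InputError(f"residue token {token!r} has no number")
    return int(digits)


def load_annotation(
    path: str | Path, native_dir: str | Path | None = None
) -> dict[str, BindingSiteAnnotation]:
    """Load a TSV annotation file: target_id, observed tokens, optional
    neutral tokens, optional native PDB path (for BDT coordinates).

    Columns are tab-separated; residue tokens are space-separated within a
    column.  Native PDB paths are resolved relative to ``native_dir`` (or
    the annotation file's directory) and provide per-residue heavy-atom
    coordinates keyed by residue token.
    """
    from .structure_io import parse_pdb

    path = Path(path)
    base = Path(native_dir) if native_dir is not None else path.parent
    annotations: dict[str, BindingSiteAnnotation] = {}
    for raw in path.read_text().splitlines():
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 2:
            raise InputError(f"annotation line needs >=2 tab-separated columns: {raw!r}")
        target = cols[0].strip()
        observed = {t.upper() for t in cols[1].split()}
        neutral = {t.upper() for t in cols[2].split()} if len(cols) > 2 else set()
        native_coords: dict[str, np.ndarray] = {}
        if len(cols) > 3 and cols[3].strip():
            native_path = Path(cols[3].strip())
            if not native_path.is_absolute():
                native_path = base / native_path
            native, _ = parse_pdb(native_path, target_id=target)
            for res in native.residues:
                native_coords[res.token()] = res.heavy_coords()
                native_coords.setdefault(str(res.seq_num), res.heavy_coords())
        annotations[target] = BindingSiteAnnotation(
            target_id=target, observed_residues=observed,
            neutral_residues=neutral, native_coords=native_coords,
        )
    if not annotations:
        raise InputError(f"no annotations found in {path}")
    return annotations
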