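"""Landmark morphometrics: TPS I/O, coronoid height, GPA, centroid size, PCA.

Mandibles are described by 16 two-dimensional landmarks digitized with a
physical scale (mm per coordinate unit).  The coronoid height — the
diagnostic size measurement — is the distance between landmarks 1 and 7
(1-based numbering throughout).  Shape analysis uses a full generalized
Procrustes fit (translation, unit-centroid-size scaling, optimal rotation,
reflections disallowed) followed by principal components of the covariance
matrix of the Procrustes coordinates.  Partial configurations retaining only
landmarks 1 and 7 can still be measured and classified but are excluded from
the Procrustes fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("pelletpop")

N_LANDMARKS = 16

#: coronoid-height classification bounds in mm:
#: <= ANOMALUS_MAX -> anomalus; [FODIENS_MIN, FODIENS_MAX] -> fodiens;
#: > FODIENS_MAX -> niethammeri; the open gap (ANOMALUS_MAX, FODIENS_MIN)
#: is deliberately left "ambiguous".
DEFAULT_THRESHOLDS = (4.70, 4.80, 5.35)


class TpsParseError(ValueError):
    """Raised for malformed TPS records, naming the offending record."""


@dataclass
class LandmarkConfiguration:
    """One specimen's 2D landmarks with physical scale.

    ``points`` is an (n_landmarks, 2) array; missing landmarks are NaN rows.
    ``scale`` converts coordinate units to mm.
    """

    sample_id: str
    points: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(f"{self.sample_id}: points must be (k, 2)")
        if self.scale <= 0:
            raise ValueError(f"{self.sample_id}: scale must be positive")
        finite = np.isfinite(self.points)
        if not (finite.all(axis=1) | (~finite).all(axis=1)).all():
            raise ValueError(f"{self.sample_id}: landmarks must be fully present or fully missing")

    @property
    def complete(self) -> bool:
        return bool(np.isfinite(self.points).all())

    def has_landmark(self, num: int) -> bool:
        """1-based landmark presence."""
        return bool(np.isfinite(self.points[num - 1]).all())

    def landmark(self, num: int) -> np.ndarray:
        """1-based landmark accessor."""
        if not self.has_landmark(num):
            raise ValueError(f"{self.sample_id}: landmark {num} missing")
        return self.points[num - 1]


def read_tps(path, n_landmarks: int = N_LANDMARKS) -> list[LandmarkConfiguration]:
    """Read a TPS file (LM=, coordinate lines, optional ID= and SCALE=).

    An ``LM=2`` block is interpreted as a partial configuration retaining
    landmarks 1 and 7 only (broken mandibles on which only the coronoid
    height is measurable).  A missing SCALE defaults to 1.0 with a warning.
    """
    configs = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    block = 0
    while i < len(lines):
        if not lines[i].upper().startswith("LM="):
            raise TpsParseError(f"{path}: expected LM= at line {i + 1}, got {lines[i]!r}")
        block += 1
        lm = int(lines[i].split("=", 1)[1])
        i += 1
        coords = []
        while i < len(lines) and not ("=" in lines[i] and not _is_coord(lines[i])):
            if not _is_coord(lines[i]):
                break
            coords.append([float(v) for v in lines[i].split()])
            i += 1
        sample_id = f"specimen_{block}"
        scale = None
        while i < len(lines) and "=" in lines[i] and not lines[i].upper().startswith("LM="):
            key, val = lines[i].split("=", 1)
            key = key.strip().upper()
            if key == "ID":
                sample_id = val.strip()
            elif key == "SCALE":
                scale = float(val)
            i += 1
        if len(coords) != lm:
            raise TpsParseError(
                f"record {sample_id!r}: LM={lm} but {len(coords)} coordinate lines")
        if scale is None:
            logger.warning("record %s: missing SCALE, defaulting to 1.0", sample_id)
            scale = 1.0
        points = np.full((n_landmarks, 2), np.nan)
        if lm == n_landmarks:
            points[:] = coords
        elif lm == 2:
            points[0] = coords[0]
            points[6] = coords[1]
        else:
            raise TpsParseError(
                f"record {sample_id!r}: LM={lm} not supported (expect {n_landmarks} or 2)")
        configs.append(LandmarkConfiguration(sample_id=sample_id, points=points, scale=scale))
    return configs


def _is_coord(line: str) -> bool:
    parts = line.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0]); float(parts[1])
    except ValueError:
        return False
    return True


def write_tps(configs: list[LandmarkConfiguration], path) -> None:
    """Write configurations as TPS blocks; partial ones as LM=2 (landmarks 1, 7)."""
    with open(path, "w") as fh:
        for cfg in configs:
            if cfg.complete:
                pts = cfg.points
            else:
                pts = cfg.points[[0, 6]]
                if not np.isfinite(pts).all():
                    raise ValueError(f"{cfg.sample_id}: partial config lacks landmarks 1/7")
            fh.write(f"LM={len(pts)}\n")
            for x, y in pts:
                fh.write(f"{x:.10g} {y:.10g}\n")
            fh.write(f"ID={cfg.sample_id}\n")
            fh.write(f"SCALE={cfg.scale:.10g}\n")


# ---------------------------------------------------------------------------
# measurements and classification

def coronoid_height(config: LandmarkConfiguration) -> float:
    """Distance between landmarks 1 and 7, in mm (coordinate units x scale)."""
    p1 = config.landmark(1)
    p7 = config.landmark(7)
    return float(np.linalg.norm(p7 - p1) * config.scale)


def classify_taxon(ch: float, thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS) -> str:
    """Classify a coronoid height (mm) into a taxon label.

    Returns one of ``anomalus`` / ``fodiens`` / ``niethammeri`` /
    ``ambiguous`` (the open interval between the anomalus maximum and the
    fodiens minimum, for which no assignment rule exists).
    """
    t_anom, t_fod_lo, t_fod_hi = thresholds
    if not (t_anom < t_fod_lo <= t_fod_hi):
        raise ValueError("thresholds must be strictly increasing")
    if not np.isfinite(ch) or ch <= 0:
        raise ValueError(f"coronoid height must be positive, got {ch}")
    if ch <= t_anom:
        return "anomalus"
    if ch < t_fod_lo:
        return "ambiguous"
    if ch <= t_fod_hi:
        return "fodiens"
    return "niethammeri"


def centroid_size(config: LandmarkConfiguration, use_scale: bool = True) -> float:
    """sqrt of summed squared landmark distances to the centroid, x scale."""
    pts = config.points[np.isfinite(config.points).all(axis=1)]
    if len(pts) < 2:
        raise ValueError(f"{config.sample_id}: not enough landmarks for centroid size")
    cs = float(np.sqrt(((pts - pts.mean(axis=0)) ** 2).sum()))
    if cs == 0:
        raise ValueError(f"{config.sample_id}: degenerate configuration (all points identical)")
    return cs * config.scale if use_scale else cs


# ---------------------------------------------------------------------------
# generalized Procrustes analysis

@dataclass
class ProcrustesResult:
    sample_ids: list[str]
    mean_shape: np.ndarray            # (k, 2), unit centroid size
    aligned: np.ndarray               # (n, k, 2) Procrustes coordinates
    centroid_sizes: np.ndarray        # (n,), in mm
    iterations: int
    converged: bool


def _optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Rotation R minimizing ||A R - B||_F, reflections disallowed."""
    M = A.T @ B
    U, _, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    return U @ D @ Vt


def procrustes_fit(configs: list[LandmarkConfiguration], tol: float = 1e-10,
                   max_iter: int = 100) -> ProcrustesResult:
    """Full generalized Procrustes superimposition.

    Each configuration is centered and scaled to unit centroid size, then
    iteratively rotated onto the running mean shape (closed-form 2D
    orthogonal solution, no reflections); the mean is re-estimated and
    re-normalized until it changes by less than ``tol`` (Frobenius) or
    ``max_iter`` iterations.
    """
    if len(configs) < 2:
        raise ValueError("Procrustes fit needs at least 2 configurations")
    k = configs[0].points.shape[0]
    X = []
    sizes = []
    for cfg in configs:
        if not cfg.complete:
            raise ValueError(f"{cfg.sample_id}: incomplete configuration in Procrustes fit")
        pts = cfg.points - cfg.points.mean(axis=0)
        cs = np.sqrt((pts ** 2).sum())
        if cs == 0:
            raise ValueError(f"{cfg.sample_id}: degenerate configuration (centroid size 0)")
        X.append(pts / cs)
        sizes.append(cs * cfg.scale)
    X = np.array(X)
    mean = X[0].copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(len(X)):
            X[i] = X[i] @ _optimal_rotation(X[i], mean)
        new_mean = X.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        new_mean /= np.sqrt((new_mean ** 2).sum())
        new_mean = new_mean @ _optimal_rotation(new_mean, mean)
        change = np.linalg.norm(new_mean - mean)
        mean = new_mean
        if change < tol:
            converged = True
        if change < 1e-14:  # polish to the fixed point for order invariance
            break
    for i in range(len(X)):
        X[i] = X[i] @ _optimal_rotation(X[i], mean)
    # reported mean shape is the coordinate-wise mean of the aligned set
    return ProcrustesResult(
        sample_ids=[c.sample_id for c in configs],
        mean_shape=X.mean(axis=0), aligned=X, centroid_sizes=np.array(sizes),
        iterations=it, converged=converged,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Frobenius distance between two aligned shapes."""
    return float(np.linalg.norm(a - b))


# ---------------------------------------------------------------------------
# shape PCA

@dataclass
class PcaResult:
    sample_ids: list[str]
    scores: np.ndarray             # (n, n_components)
    loadings: np.ndarray           # (n_components, 2k)
    variance_fractions: np.ndarray


def shape_pca(proc: ProcrustesResult) -> PcaResult:
    """PCA of the covariance matrix of flattened Procrustes coordinates.

    At most ``min(n - 1, 2k - 4)`` nontrivial components are retained: four
    degrees of freedom are absorbed by the 2D similarity fit.
    """
    n, k, _ = proc.aligned.shape
    if n < 3:
        raise ValueError("shape PCA needs at least 3 samples")
    flat = proc.aligned.reshape(n, 2 * k)
    centered = flat - flat.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_comp = min(n - 1, 2 * k - 4)
    scores = centered @ eigvec[:, :n_comp]
    fractions = eigval[:n_comp] / eigval[eigval > 0].sum()
    return PcaResult(sample_ids=list(proc.sample_ids), scores=scores,
                     loadings=eigvec[:, :n_comp].T, variance_fractions=fractions)


def permutation_group_test(values: np.ndarray, labels, n_perm: int = 999,
                           seed: int | None = None) -> float:
    """Two-group permutation p-value for |mean difference| of a score.

    Used to ask whether e.g. PC1 scores or centroid sizes separate two
    groups; p = (1 + #{permuted |diff| >= observed}) / (n_perm + 1).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    mask = labels == groups[0]
    obs = abs(values[mask].mean() - values[~mask].mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(mask)
        d = abs(values[perm].mean() - values[~perm].mean())
        if d >= obs:
            count += 1
    return (1 + count) / (n_perm + 1)
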