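"""Environment-specific null models for binary occurrence data.

The null hypothesis is that taxa occur independently, with per-taxon and
per-sample propensities but no interactions.  Three ingredients implement it:

* a maximum-entropy margin model ``pi_ia = logistic(alpha_i + beta_a)`` whose
  expected row and column totals match the observed ones (the occurrence
  probability of genus *i* in sample *a* absent any interaction);
* fixed-margin random matrix ensembles drawn by curveball trades, used to
  learn the null distribution of aggregation scores;
* the aggregation score ``S_ij = -log P(X >= N)`` where ``X`` is the
  Poisson-binomial count of samples in which the pair would co-occur by
  chance (per-sample success probability ``pi_ia * pi_ja``) and ``N`` the
  observed co-occurrence count.

Raw scores depend strongly on how cosmopolitan the two taxa are, so they are
standardized into Z-scores against null pairs of similar cosmopolitanism
(quantile bins of ``log(n_i * n_j + 1)``), and a Z cutoff is calibrated so the
empirical false positive rate on the null ensemble does not exceed a target
(default 1e-4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConvergenceError, InvariantError
from .io_model import OccurrenceTable, SampleAnnotation

__all__ = [
    "ProbabilityMatrix",
    "NullEnsemble",
    "ScoreCalibration",
    "fit_null_probabilities",
    "fit_environment_probabilities",
    "sample_null_matrices",
    "poisson_binomial_pmf",
    "cooccurrence_tail",
    "aggregation_score",
    "pair_survival_batch",
    "calibrate_scores",
    "pair_zscore",
]

SCORE_FLOOR = 1e-300  # tail probabilities are clamped here so -log stays finite


@dataclass
class ProbabilityMatrix:
    """Null occurrence probabilities aligned with one occurrence table."""

    genus_ids: list[str]
    sample_ids: list[str]
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (len(self.genus_ids), len(self.sample_ids)):
            raise InvariantError("probability matrix shape mismatch")
        if (self.pi < 0).any() or (self.pi > 1).any():
            raise InvariantError("probabilities outside [0,1]")


@dataclass
class NullEnsemble:
    """Fixed-margin random binary matrices sharing one source table's margins."""

    matrices: np.ndarray  # (n, genera, samples) uint8
    row_totals: np.ndarray
    col_totals: np.ndarray

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=np.uint8)

    def __len__(self) -> int:
        return self.matrices.shape[0]


# ---------------------------------------------------------------------------
# margin model


def fit_null_probabilities(
    table: OccurrenceTable, tol: float = 1e-6, max_iter: int = 1000
) -> ProbabilityMatrix:
    """Fit ``pi_ia = logistic(alpha_i + beta_a)`` by alternating Newton steps
    so expected margins match observed margins to relative tolerance ``tol``.

    The table should contain the samples of a single environment subtype, so
    the model captures that habitat's occupancy structure.  Saturated margins
    (all-zero or all-one rows/columns) are peeled off exactly before fitting.
    """
    X = table.X.astype(float)
    G, M = X.shape
    if G == 0 or M == 0:
        raise InvariantError("empty table")
    pi = np.zeros((G, M))
    grow = np.ones(G, dtype=bool)
    scol = np.ones(M, dtype=bool)
    # peel saturated rows/columns: their probabilities are forced to 0 or 1
    changed = True
    while changed:
        changed = False
        sub = X[np.ix_(grow, scol)]
        if sub.size == 0:
            break
        r = sub.sum(axis=1)
        c = sub.sum(axis=0)
        gidx = np.flatnonzero(grow)
        sidx = np.flatnonzero(scol)
        full_rows = gidx[r == sub.shape[1]]
        zero_rows = gidx[r == 0]
        if full_rows.size or zero_rows.size:
            pi[np.ix_(full_rows, sidx)] = 1.0
            grow[full_rows] = False
            grow[zero_rows] = False
            changed = True
            continue
        full_cols = sidx[c == sub.shape[0]]
        zero_cols = sidx[c == 0]
        if full_cols.size or zero_cols.size:
            pi[np.ix_(np.flatnonzero(grow), full_cols)] = 1.0
            scol[full_cols] = False
            scol[zero_cols] = False
            changed = True

    sub = X[np.ix_(grow, scol)]
    if sub.size:
        r = sub.sum(axis=1)
        c = sub.sum(axis=0)
        m, g = sub.shape[1], sub.shape[0]
        alpha = np.log(r / (m - r))
        beta = np.zeros(m)
        ok = False
        for _ in range(max_iter):
            P = 1.0 / (1.0 + np.exp(-(alpha[:, None] + beta[None, :])))
            fr = P.sum(axis=1) - r
            alpha -= fr / np.maximum((P * (1 - P)).sum(axis=1), 1e-12)
            P = 1.0 / (1.0 + np.exp(-(alpha[:, None] + beta[None, :])))
            fc = P.sum(axis=0) - c
            beta -= fc / np.maximum((P * (1 - P)).sum(axis=0), 1e-12)
            P = 1.0 / (1.0 + np.exp(-(alpha[:, None] + beta[None, :])))
            res = max(
                np.max(np.abs(P.sum(axis=1) - r) / r),
                np.max(np.abs(P.sum(axis=0) - c) / c),
            )
            if res < tol:
                ok = True
                break
        if not ok:
            raise ConvergenceError(
                f"margin fit did not converge: worst relative residual {res:.3g}"
            )
        pi[np.ix_(grow, scol)] = np.clip(P, 0.0, 1.0)
    return ProbabilityMatrix(list(table.genus_ids), list(table.sample_ids), pi)


def fit_environment_probabilities(
    table: OccurrenceTable,
    annotations: Iterable[SampleAnnotation],
    tol: float = 1e-6,
) -> ProbabilityMatrix:
    """Fit one null model per environment subtype present in ``table`` and
    stitch the per-subtype probability columns back into a single matrix."""
    ann = {a.sample_id: a for a in annotations}
    missing = [s for s in table.sample_ids if s not in ann]
    if missing:
        raise InvariantError(f"samples without annotation: {missing[:5]}")
    pi = np.zeros(table.X.shape)
    col = {s: a for a, s in enumerate(table.sample_ids)}
    subtypes: dict[str, list[str]] = {}
    for s in table.sample_ids:
        subtypes.setdefault(ann[s].env_subtype, []).append(s)
    for samples in subtypes.values():
        sub = table.subset_samples(samples)
        sub_pi = fit_null_probabilities(sub, tol=tol)
        for s, a in zip(samples, range(len(samples))):
            pi[:, col[s]] = sub_pi.pi[:, a]
    return ProbabilityMatrix(list(table.genus_ids), list(table.sample_ids), pi)


# ---------------------------------------------------------------------------
# fixed-margin sampling (curveball trades)


def _curveball_trade(rows: list[set[int]], rng: np.random.Generator) -> None:
    n = len(rows)
    i, j = rng.choice(n, size=2, replace=False)
    a, b = rows[i], rows[j]
    shared = a & b
    ua = list(a - shared)
    ub = list(b - shared)
    if not ua and not ub:
        return
    pool = ua + ub
    rng.shuffle(pool)
    rows[i] = shared | set(pool[: len(ua)])
    rows[j] = shared | set(pool[len(ua):])


def sample_null_matrices(
    table: OccurrenceTable,
    n: int = 1000,
    seed: int | np.random.Generator = 0,
    burn_in: int | None = None,
    thin: int | None = None,
) -> NullEnsemble:
    """Draw ``n`` random binary matrices with exactly the row and column
    totals of ``table`` using seeded curveball trades.

    ``burn_in`` defaults to 5x the number of ones in the matrix, ``thin``
    (trades between consecutive samples) to the number of genera.
    """
    if n < 0:
        raise InvariantError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    G, M = table.X.shape
    nnz = int(table.X.sum())
    if burn_in is None:
        burn_in = 5 * nnz
    if thin is None:
        thin = max(G, 10)
    rows = [set(np.flatnonzero(table.X[i]).tolist()) for i in range(G)]
    out = np.zeros((n, G, M), dtype=np.uint8)
    if G >= 2:
        for _ in range(burn_in):
            _curveball_trade(rows, rng)
    for k in range(n):
        if G >= 2:
            for _ in range(thin):
                _curveball_trade(rows, rng)
        for i, cols in enumerate(rows):
            out[k, i, list(cols)] = 1
    return NullEnsemble(out, table.X.sum(axis=1), table.X.sum(axis=0))


# ---------------------------------------------------------------------------
# Poisson-binomial machinery


def poisson_binomial_pmf(probs: Sequence[float]) -> np.ndarray:
    """Exact count distribution of a sum of independent Bernoulli trials,
    by dynamic programming over the count support."""
    p = np.asarray(probs, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise InvariantError("probability outside [0,1]")
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    w = 1
    for pa in p:
        pmf[1 : w + 1] = pmf[1 : w + 1] * (1 - pa) + pmf[:w] * pa
        pmf[0] *= 1 - pa
        w += 1
    return pmf


def cooccurrence_tail(probs: Sequence[float], n_obs: int) -> float:
    """P(X >= n_obs) for the Poisson-binomial count with the given per-sample
    success probabilities, computed exactly (summed from the top of the pmf
    so tiny tails do not cancel)."""
    p = np.asarray(probs, dtype=float)
    if not (0 <= n_obs <= p.size):
        raise InvariantError(f"n_obs {n_obs} outside [0, {p.size}]")
    if (p < 0).any() or (p > 1).any():
        raise InvariantError("probability outside [0,1]")
    if n_obs == 0:
        return 1.0
    pmf = poisson_binomial_pmf(p)
    return float(min(1.0, pmf[n_obs:].sum()))


def aggregation_score(
    table: OccurrenceTable,
    pi: ProbabilityMatrix,
    i: int | str,
    j: int | str,
) -> float:
    """Aggregation score ``S_ij`` of a pair of genera: the negative log of
    the null probability of co-occurring in at least the observed number of
    samples."""
    ii = table.genus_index(i) if isinstance(i, str) else i
    jj = table.genus_index(j) if isinstance(j, str) else j
    if ii == jj:
        raise InvariantError("aggregation score of a genus with itself")
    n_obs = int((table.X[ii] & table.X[jj]).sum())
    tail = cooccurrence_tail(pi.pi[ii] * pi.pi[jj], n_obs)
    return float(-np.log(max(tail, SCORE_FLOOR)))


def pair_survival_batch(P_u: np.ndarray, P_v: np.ndarray) -> np.ndarray:
    """Survival tables ``sf[pair, k] = P(X_pair >= k)`` for many pairs at
    once.

    ``P_u`` and ``P_v`` are (n_pairs, M) arrays of the two members' null
    probabilities; the per-sample co-occurrence probability is their product.
    Vectorized DP across pairs; the active count window grows with the number
    of processed samples, which roughly halves the work.
    """
    P_u = np.atleast_2d(np.asarray(P_u, dtype=float))
    P_v = np.atleast_2d(np.asarray(P_v, dtype=float))
    n_pairs, M = P_u.shape
    pmf = np.zeros((n_pairs, M + 1))
    pmf[:, 0] = 1.0
    w = 1
    for a in range(M):
        p = (P_u[:, a] * P_v[:, a])[:, None]
        pmf[:, 1 : w + 1] = pmf[:, 1 : w + 1] * (1 - p) + pmf[:, :w] * p
        pmf[:, 0] *= (1 - p)[:, 0]
        w += 1
    sf = np.cumsum(pmf[:, ::-1], axis=1)[:, ::-1]
    return np.minimum(sf, 1.0)


def scores_from_survival(sf: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Aggregation scores from precomputed survival tables and observed
    co-occurrence counts (counts may be (n_pairs,) or (n_pairs, n_matrices))."""
    counts = np.asarray(counts)
    tails = np.take_along_axis(
        sf, counts.reshape(sf.shape[0], -1).astype(np.int64), axis=1
    )
    tails = tails.reshape(counts.shape)
    return -np.log(np.maximum(tails, SCORE_FLOOR))


# ---------------------------------------------------------------------------
# calibration


@dataclass
class ScoreCalibration:
    """Cosmopolitanism-binned null score statistics and the Z cutoff.

    Pairs are assigned to bins by ``c = log(n_u * n_v + 1)`` where ``n`` is
    how many samples each member occupies.  Interior edges partition the real
    line (the outermost bins are unbounded), so every pair maps to exactly
    one bin.
    """

    bin_edges: np.ndarray  # interior edges, length n_bins - 1
    bin_mean: np.ndarray
    bin_sd: np.ndarray
    z_cutoff: float
    target_fpr: float = 1e-4
    n_null_scores: int = 0

    def bin_of(self, n_u, n_v) -> np.ndarray:
        c = np.log(np.asarray(n_u, dtype=float) * np.asarray(n_v, dtype=float) + 1.0)
        if not np.isfinite(c).all():
            raise InvariantError("non-finite cosmopolitanism; bin undefined")
        return np.searchsorted(self.bin_edges, c, side="right")

    def zscore(self, score, n_u, n_v):
        b = self.bin_of(n_u, n_v)
        return (np.asarray(score, dtype=float) - self.bin_mean[b]) / self.bin_sd[b]

    def save(self, path) -> None:
        import json

        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "bin_edges": self.bin_edges.tolist(),
                    "bin_mean": self.bin_mean.tolist(),
                    "bin_sd": self.bin_sd.tolist(),
                    "z_cutoff": self.z_cutoff,
                    "target_fpr": self.target_fpr,
                    "n_null_scores": self.n_null_scores,
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, path) -> "ScoreCalibration":
        import json

        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            np.asarray(d["bin_edges"]),
            np.asarray(d["bin_mean"]),
            np.asarray(d["bin_sd"]),
            float(d["z_cutoff"]),
            float(d["target_fpr"]),
            int(d["n_null_scores"]),
        )


def _fpr_cutoff(z: np.ndarray, target_fpr: float) -> float:
    """Smallest observed null Z such that the fraction of null Z >= cutoff is
    at most ``target_fpr`` (ties handled by counting)."""
    zs = np.sort(z)
    N = zs.size
    i = int(np.ceil(N * (1.0 - target_fpr)))
    if i >= N:
        i = N - 1
    # advance past ties so the <= target guarantee holds
    while i < N:
        frac = (N - np.searchsorted(zs, zs[i], side="left")) / N
        if frac <= target_fpr:
            return float(zs[i])
        i += 1
    return float(zs[-1] + 1.0)


def calibrate_scores(
    real_table: OccurrenceTable,
    pi: ProbabilityMatrix,
    ensemble: NullEnsemble,
    target_fpr: float = 1e-4,
    n_bins: int = 20,
    min_pairs_per_bin: int = 50,
) -> ScoreCalibration:
    """Learn per-bin null score statistics and the significance cutoff.

    Aggregation scores are computed for every unordered pair of genera in
    every ensemble matrix (against the same fitted ``pi``), binned by pair
    cosmopolitanism, standardized per bin, and the Z cutoff chosen so that
    the empirical null FPR does not exceed ``target_fpr``.  Bins with too few
    null pairs or zero score variance are merged with a neighbour.
    """
    if len(ensemble) == 0:
        raise InvariantError("empty null ensemble")
    X = real_table.X
    G, M = X.shape
    iu, ju = np.triu_indices(G, k=1)
    n = X.sum(axis=1).astype(float)  # cosmopolitanism is margin-preserved
    c = np.log(n[iu] * n[ju] + 1.0)

    sf = pair_survival_batch(pi.pi[iu], pi.pi[ju])
    mats = ensemble.matrices.astype(np.float64)
    counts = np.einsum("kim,kjm->kij", mats, mats, optimize=True)[:, iu, ju]
    counts = counts.T.astype(np.int64)  # (n_pairs, n_matrices)
    scores = scores_from_survival(sf, counts)

    # quantile bins over pair cosmopolitanism, then merge deficient bins
    qs = np.quantile(c, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    while True:
        bins = np.searchsorted(edges, c, side="right")
        nb = edges.size + 1
        count_pairs = np.bincount(bins, minlength=nb)
        mean = np.zeros(nb)
        sd = np.zeros(nb)
        for b in range(nb):
            sel = scores[bins == b]
            if sel.size:
                mean[b] = sel.mean()
                sd[b] = sel.std()
        bad = np.flatnonzero((count_pairs * len(ensemble) < min_pairs_per_bin) | (sd <= 0))
        if bad.size == 0 or nb == 1:
            break
        b = bad[0]
        # merging bin b with its lower neighbour == removing edge b-1
        drop = b - 1 if b > 0 else 0
        edges = np.delete(edges, drop)
    if np.any(sd <= 0):
        raise InvariantError("degenerate null score variance after bin merging")

    z = (scores - mean[bins][:, None]) / sd[bins][:, None]
    cutoff = _fpr_cutoff(z.ravel(), target_fpr)
    return ScoreCalibration(
        bin_edges=edges,
        bin_mean=mean,
        bin_sd=sd,
        z_cutoff=cutoff,
        target_fpr=target_fpr,
        n_null_scores=z.size,
    )


def pair_zscore(
    score: float, n_u: float, n_v: float, calibration: ScoreCalibration
) -> tuple[float, bool]:
    """Standardize a score against null pairs of similar cosmopolitanism.

    Returns ``(z, significant)`` where significance means exceeding the
    calibrated cutoff.  ``n_u``/``n_v`` are the members' occupancy counts.
    """
    z = float(calibration.zscore(score, n_u, n_v))
    return z, z > calibration.z_cutoff
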