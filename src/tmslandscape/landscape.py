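"""Pairwise maximum-entropy (Ising) energy-landscape analysis.

Binarized multi-region activity is modelled by the pairwise
maximum-entropy distribution

    P(sigma) = exp(-E(sigma)) / Z,
    E(sigma) = - sum_i h_i sigma_i - sum_{i<j} J_ij sigma_i sigma_j,

with sigma in {-1, +1}^M.  ``h_i`` biases region ``i`` toward activity,
``J_ij`` couples pairs of regions, and low-energy patterns are visited
often.  For the small networks considered here (M <= 12) everything is
computed by exact enumeration of the 2^M patterns: likelihood fitting,
Boltzmann probabilities, local minima ("stable states") under single-region
flips, and the disconnectivity graph joining minima at their energy
barriers.

Pattern coding convention: bit ``i`` of an integer code is region ``i``;
a set bit means the region is active (+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .networks import MAX_REGIONS, NetworkDefinition

__all__ = [
    "BinaryPatternSeries",
    "MaxEntModel",
    "EnergyLandscape",
    "DisconnectivityGraph",
    "ConvergenceError",
    "binarize",
    "fit_maxent",
    "energy",
    "energies_all",
    "boltzmann",
    "model_moments",
    "empirical_moments",
    "find_stable_states",
    "local_minima",
    "disconnectivity_graph",
    "subject_energies",
    "pattern_string",
    "code_to_spins",
    "spins_to_code",
]


class ConvergenceError(RuntimeError):
    """Raised when the maximum-entropy fit cannot match the empirical moments."""


# ---------------------------------------------------------------------------
# pattern enumeration tables
# ---------------------------------------------------------------------------


@lru_cache(maxsize=16)
def _tables(m: int):
    """Enumeration tables for M regions.

    Returns ``(spins, pairs, iu, ju)`` where ``spins`` is the
    (2^M, M) matrix of all patterns in code order and ``pairs`` the
    (2^M, M(M-1)/2) matrix of products sigma_i sigma_j for i < j.
    """
    codes = np.arange(2**m)
    spins = np.where((codes[:, None] >> np.arange(m)) & 1, 1.0, -1.0)
    iu, ju = np.triu_indices(m, k=1)
    pairs = spins[:, iu] * spins[:, ju]
    return spins, pairs, iu, ju


def pattern_string(code: int, m: int) -> str:
    """Render a pattern code as '+'/'-' characters in region order."""
    return "".join("+" if (code >> i) & 1 else "-" for i in range(m))


def code_to_spins(code: int, m: int) -> np.ndarray:
    return np.where((code >> np.arange(m)) & 1, 1.0, -1.0)


def spins_to_code(sigma: np.ndarray) -> int:
    sigma = np.asarray(sigma)
    return int(((sigma > 0).astype(np.int64) << np.arange(sigma.size)).sum())


def _codes_of(patterns: np.ndarray) -> np.ndarray:
    m = patterns.shape[1]
    return (patterns > 0).astype(np.int64) @ (1 << np.arange(m, dtype=np.int64))


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class BinaryPatternSeries:
    """A sequence of binary activity patterns over M regions.

    ``patterns`` is (n_samples, M) with values in {-1, +1}.
    """

    patterns: np.ndarray
    region_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.patterns.ndim != 2:
            raise ValueError("patterns must be 2-D (samples x regions)")
        if not np.all(np.isin(self.patterns, (-1.0, 1.0))):
            raise ValueError("patterns must contain only -1 and +1")
        if self.region_names is not None:
            self.region_names = tuple(self.region_names)
            if len(self.region_names) != self.patterns.shape[1]:
                raise ValueError("region_names length does not match patterns")

    @property
    def n_samples(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_regions(self) -> int:
        return self.patterns.shape[1]

    @property
    def codes(self) -> np.ndarray:
        return _codes_of(self.patterns)

    @property
    def counts(self) -> dict[int, int]:
        """Visit count per pattern code (only visited codes are listed)."""
        codes, counts = np.unique(self.codes, return_counts=True)
        return {int(c): int(k) for c, k in zip(codes, counts)}

    def concatenate(self, other: "BinaryPatternSeries") -> "BinaryPatternSeries":
        if self.n_regions != other.n_regions:
            raise ValueError("cannot concatenate series with different M")
        return BinaryPatternSeries(
            np.vstack([self.patterns, other.patterns]), self.region_names
        )


@dataclass
class MaxEntModel:
    """Pairwise maximum-entropy model parameters (h, J) for M regions.

    ``J`` is symmetric with an exactly-zero diagonal.  ``moment_error`` is
    the largest absolute mismatch between model and empirical moments at
    the end of fitting (NaN for hand-constructed models).
    """

    h: np.ndarray
    J: np.ndarray
    n_iter: int = 0
    moment_error: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        m = self.h.size
        if self.J.shape != (m, m):
            raise ValueError("J must be square with side len(h)")
        if not np.all(np.isfinite(self.h)) or not np.all(np.isfinite(self.J)):
            raise ValueError("model parameters must be finite")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("J must be symmetric")
        if np.any(np.diag(self.J) != 0.0):
            raise ValueError("J must have an exactly zero diagonal")

    @property
    def n_regions(self) -> int:
        return self.h.size


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------


def binarize(series, network: NetworkDefinition, window: str) -> BinaryPatternSeries:
    """Binarize a subject's ROI series over one window of a network.

    For each region the threshold is the mean of that region's values
    within the requested window (``"pre"`` or ``"post"``); values strictly
    above threshold map to +1, everything else (including exact ties) to
    -1.
    """
    missing = [r for r in network.regions if r not in series.roi_names]
    if missing:
        raise KeyError(
            f"ROI series for subject {series.subject_id!r} is missing region(s) "
            f"{missing} required by network {network.name!r}"
        )
    sl = series.window(window)
    idx = [series.roi_names.index(r) for r in network.regions]
    values = np.asarray(series.values)[idx][:, sl]
    thresholds = values.mean(axis=1, keepdims=True)
    patterns = np.where(values > thresholds, 1.0, -1.0).T
    return BinaryPatternSeries(patterns, region_names=network.regions)


# ---------------------------------------------------------------------------
# energies and probabilities
# ---------------------------------------------------------------------------


def energy(model: MaxEntModel, pattern: Sequence[float]) -> float:
    """Energy of one activity pattern, E = -h.sigma - sum_{i<j} J_ij s_i s_j."""
    sigma = np.asarray(pattern, dtype=float)
    if sigma.shape != (model.n_regions,):
        raise ValueError(
            f"pattern has length {sigma.size}, model has {model.n_regions} regions"
        )
    return float(-model.h @ sigma - 0.5 * sigma @ model.J @ sigma)


def energies_all(model: MaxEntModel) -> np.ndarray:
    """Energies of all 2^M patterns, indexed by pattern code."""
    m = model.n_regions
    if m > MAX_REGIONS:
        raise ValueError(f"M={m} exceeds the enumeration limit of {MAX_REGIONS}")
    spins, pairs, iu, ju = _tables(m)
    return -(spins @ model.h) - pairs @ model.J[iu, ju]


def boltzmann(model: MaxEntModel) -> np.ndarray:
    """Boltzmann probabilities P = exp(-E) / sum exp(-E') over all 2^M patterns."""
    neg_e = -energies_all(model)
    neg_e -= neg_e.max()  # overflow guard
    p = np.exp(neg_e)
    return p / p.sum()


def model_moments(model: MaxEntModel) -> tuple[np.ndarray, np.ndarray]:
    """Exact model moments (<sigma_i>, <sigma_i sigma_j> for i<j)."""
    spins, pairs, _, _ = _tables(model.n_regions)
    p = boltzmann(model)
    return p @ spins, p @ pairs


def empirical_moments(series) -> tuple[np.ndarray, np.ndarray]:
    """Empirical moments of a pattern series or raw (n, M) +-1 array."""
    patterns = series.patterns if isinstance(series, BinaryPatternSeries) else np.asarray(series, float)
    m = patterns.shape[1]
    _, _, iu, ju = _tables(m)
    mean = patterns.mean(axis=0)
    corr = (patterns[:, iu] * patterns[:, ju]).mean(axis=0)
    return mean, corr


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_maxent(
    binary,
    *,
    tol_moment: float = 1e-4,
    max_iter: int = 100_000,
    l2: float = 0.0,
    theta_max: float = 20.0,
    method: str = "lbfgs",
    learning_rate: float = 0.1,
) -> MaxEntModel:
    """Fit (h, J) by maximum likelihood with exact 2^M enumeration.

    The log-likelihood is concave, so the default solver is L-BFGS-B on the
    exact negative log-likelihood with box bounds ``|theta| <= theta_max``;
    ``method="gd"`` selects plain gradient ascent with step
    ``learning_rate`` instead.  Convergence means every model moment
    matches its empirical counterpart within ``tol_moment``.

    Degenerate data (a region constant over all samples, or perfectly
    correlated pairs) put the empirical moments on the boundary of the
    achievable set; the corresponding parameters then run to the
    ``theta_max`` clip and a warning is issued instead of an error.  A
    small ridge ``l2`` (penalty ``l2 * ||theta||^2`` added to the
    per-sample negative log-likelihood) stabilizes fits on short series at
    the cost of a proportional moment mismatch.
    """
    patterns = binary.patterns if isinstance(binary, BinaryPatternSeries) else np.asarray(binary, float)
    if patterns.ndim != 2 or patterns.shape[0] < 1:
        raise ValueError("need a non-empty (n_samples, M) pattern array")
    n, m = patterns.shape
    if m > MAX_REGIONS:
        raise ValueError(f"M={m} exceeds the enumeration limit of {MAX_REGIONS}")

    spins, pairs, iu, ju = _tables(m)
    codes = _codes_of(patterns)
    p_emp = np.bincount(codes, minlength=2**m) / n
    m_emp = p_emp @ spins
    c_emp = p_emp @ pairs
    emp = np.concatenate([m_emp, c_emp])

    if np.any(np.abs(m_emp) >= 1.0):
        which = [i for i in range(m) if abs(m_emp[i]) >= 1.0]
        warnings.warn(
            f"region(s) {which} are constant across all samples; "
            f"their fields are clipped at +-{theta_max}",
            RuntimeWarning,
            stacklevel=2,
        )

    def objective(theta: np.ndarray):
        neg_e = spins @ theta[:m] + pairs @ theta[m:]
        lz = logsumexp(neg_e)
        p = np.exp(neg_e - lz)
        f = lz - emp @ theta + l2 * (theta @ theta)
        g = np.concatenate([p @ spins, p @ pairs]) - emp + 2.0 * l2 * theta
        return f, g

    n_params = m + m * (m - 1) // 2
    if method == "lbfgs":
        res = minimize(
            objective,
            np.zeros(n_params),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-theta_max, theta_max)] * n_params,
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
        )
        theta, n_iter = res.x, int(res.nit)
    elif method == "gd":
        theta = np.zeros(n_params)
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            _, g = objective(theta)
            theta = np.clip(theta - learning_rate * g, -theta_max, theta_max)
            if np.max(np.abs(g)) <= tol_moment:
                break
    else:
        raise ValueError(f"unknown method {method!r}")

    neg_e = spins @ theta[:m] + pairs @ theta[m:]
    p = np.exp(neg_e - logsumexp(neg_e))
    mom = np.concatenate([p @ spins, p @ pairs])
    moment_error = float(np.max(np.abs(mom - emp)))
    converged = moment_error <= tol_moment
    at_bounds = bool(np.any(np.abs(theta) >= theta_max - 1e-9))
    if not converged and not at_bounds and l2 == 0.0:
        raise ConvergenceError(
            f"maximum-entropy fit did not reach tol_moment={tol_moment:g}: "
            f"max moment mismatch {moment_error:.3g} after {n_iter} iterations"
        )

    J = np.zeros((m, m))
    J[iu, ju] = theta[m:]
    J += J.T
    return MaxEntModel(
        h=theta[:m], J=J, n_iter=n_iter, moment_error=moment_error, converged=converged
    )


# ---------------------------------------------------------------------------
# landscape enumeration
# ---------------------------------------------------------------------------


def local_minima(energies: np.ndarray) -> np.ndarray:
    """Codes of patterns whose energy is <= that of every single-flip neighbor."""
    n_states = energies.size
    m = int(np.log2(n_states))
    codes = np.arange(n_states)
    ok = np.ones(n_states, dtype=bool)
    for i in range(m):
        ok &= energies <= energies[codes ^ (1 << i)]
    return codes[ok]


@dataclass
class EnergyLandscape:
    """Exhaustive energy landscape of a fitted model over all 2^M patterns."""

    model: MaxEntModel
    energies: np.ndarray
    probabilities: np.ndarray
    local_minima: np.ndarray

    @classmethod
    def from_model(cls, model: MaxEntModel) -> "EnergyLandscape":
        e = energies_all(model)
        return cls(
            model=model,
            energies=e,
            probabilities=boltzmann(model),
            local_minima=local_minima(e),
        )

    @property
    def n_regions(self) -> int:
        return self.model.n_regions


def find_stable_states(landscape: EnergyLandscape, k: int | None = None) -> list[int]:
    """Local minima ranked by energy (ties broken by ascending code).

    ``k`` truncates the list to the k least-energy minima; ``None`` keeps
    all of them.
    """
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    minima = landscape.local_minima
    order = np.lexsort((minima, landscape.energies[minima]))
    ranked = [int(c) for c in minima[order]]
    return ranked if k is None else ranked[:k]


@dataclass
class DisconnectivityGraph:
    """Tree of local minima joined at their connecting energy barriers.

    ``merges`` lists (min_a, min_b, barrier) events in ascending barrier
    order, where each minimum code is the lowest-energy minimum of the
    basin it represents at merge time.  ``barriers`` maps every unordered
    minima pair to the lowest energy level at which single-flip paths
    connect them.
    """

    minima: list[int]
    merges: list[tuple[int, int, float]]
    barriers: dict[tuple[int, int], float]

    def barrier(self, a: int, b: int) -> float:
        if a == b:
            raise ValueError("barrier is defined between distinct minima")
        return self.barriers[(min(a, b), max(a, b))]


def disconnectivity_graph(landscape: EnergyLandscape) -> DisconnectivityGraph:
    """Build the disconnectivity graph by threshold filtration.

    States are activated in ascending energy order; a union-find structure
    tracks connected components of the activated part of the hypercube.
    When two components that each contain a local minimum merge, the
    activation energy is the barrier between every cross pair of their
    minima (the minimax single-flip path value).
    """
    energies = landscape.energies
    m = landscape.n_regions
    minima_set = set(int(c) for c in landscape.local_minima)

    parent = np.full(energies.size, -1, dtype=np.int64)  # -1 = not yet activated

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    comp_minima: dict[int, list[int]] = {}
    barriers: dict[tuple[int, int], float] = {}
    merges: list[tuple[int, int, float]] = []

    def representative(members: list[int]) -> int:
        return min(members, key=lambda c: (energies[c], c))

    order = np.lexsort((np.arange(energies.size), energies))
    for code in order:
        code = int(code)
        parent[code] = code
        comp_minima[code] = [code] if code in minima_set else []
        for i in range(m):
            nb = code ^ (1 << i)
            if parent[nb] < 0:
                continue
            ra, rb = find(code), find(nb)
            if ra == rb:
                continue
            mins_a, mins_b = comp_minima.pop(ra), comp_minima.pop(rb)
            if mins_a and mins_b:
                level = float(energies[code])
                for a in mins_a:
                    for b in mins_b:
                        barriers[(min(a, b), max(a, b))] = level
                merges.append((representative(mins_a), representative(mins_b), level))
            parent[ra] = rb
            comp_minima[rb] = mins_a + mins_b

    minima_sorted = find_stable_states(landscape)
    return DisconnectivityGraph(minima=minima_sorted, merges=merges, barriers=barriers)


# ---------------------------------------------------------------------------
# subject-wise energies
# ---------------------------------------------------------------------------


def subject_energies(
    series_list: Iterable,
    network: NetworkDefinition,
    selected_patterns: Sequence[int],
    *,
    per_subject_model: bool = True,
    group_models: Mapping[tuple[str, str], MaxEntModel] | None = None,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Energies of the selected patterns for every subject and condition.

    For each subject and each window (pre/post) a subject-level model is
    fitted to that subject's binarized series and the energies of the
    selected group-level patterns are evaluated under it.  With
    ``per_subject_model=False`` the group-level model for the subject's
    (group, condition) cell is used instead (``group_models`` required).

    Returns a tidy frame with columns subject, group, site, condition,
    network, pattern_code, pattern_string, energy.
    """
    if not per_subject_model and group_models is None:
        raise ValueError("group_models is required when per_subject_model=False")
    fit_kwargs = dict(fit_kwargs or {})
    m = network.n_regions
    rows = []
    for rs in series_list:
        for condition in ("pre", "post"):
            bp = binarize(rs, network, condition)
            if per_subject_model:
                try:
                    model = fit_maxent(bp, **fit_kwargs)
                except ConvergenceError as exc:
                    raise ConvergenceError(
                        f"subject {rs.subject_id!r}, condition {condition!r}: {exc}"
                    ) from exc
            else:
                model = group_models[(rs.group, condition)]
            for code in selected_patterns:
                rows.append(
                    {
                        "subject": rs.subject_id,
                        "group": rs.group,
                        "site": rs.site,
                        "condition": condition,
                        "network": network.name,
                        "pattern_code": int(code),
                        "pattern_string": pattern_string(int(code), m),
                        "energy": energy(model, code_to_spins(int(code), m)),
                    }
                )
    return pd.DataFrame(rows)
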