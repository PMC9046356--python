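"""Nonparametric permutation inference for laminar morphometry.

The model is a one-way layout ``Y_ij = mu + tau_j + eps_ij`` where both the
group location ``tau_j`` and the group scale ``sigma2_j`` may differ under
the alternative, while under the null the observations are exchangeable
across groups.  Each variable is tested by permutation with a joint
location+scale statistic (Fisher combination of a between-group-means
partial and a between-group-dispersions partial); variables are combined
within the domains size / shape / density, and domains into a global test,
by the nonparametric-combination (NPC) method with the Fisher combining
function ``-2 sum log p`` — all partial tests evaluated on the *same*
synchronized permutations.  Pairwise group comparisons use permutations
constrained to the two groups' rows, with Shaffer's logically-constrained
step-down multiplicity adjustment.

p-values use the add-one convention ``(1 + #{T* >= T}) / (B + 1)``; when
the number of distinct group relabelings is at most B the permutation
distribution is enumerated exhaustively and the p-value is exact.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "PermutationScheme",
    "PermutationTestResult",
    "LayerResult",
    "StudyResult",
    "DOMAINS_DEFAULT",
    "build_scheme",
    "permutation_test",
    "npc_fisher_combine",
    "pairwise_tests",
    "shaffer_multipliers",
    "shaffer_adjust",
    "classify_eye_position",
    "run_grouping_analysis",
]

#: Default variable-to-domain map: the three analysis domains.
DOMAINS_DEFAULT: dict[str, tuple[str, ...]] = {
    "size": ("area_um2", "perimeter_um"),
    "shape": ("circularity", "solidity", "extent", "inv_ar"),
    "density": ("density_50um",),
}

EYE_POSITION_CLASSES = ("frontal-eyed", "wide-field", "lateral-eyed")


def classify_eye_position(
    angle_deg: float, frontal_max: float = 60.0, wide_max: float = 150.0
) -> str:
    """Eye-position class from the inter-orbital-plane angle (degrees).

    Frontal-eyed up to 60°, wide-field up to 150°, lateral-eyed beyond:
    the canonical classes are centred near 20° (frontal binocular),
    100–150° (wide field) and 150–180° (lateral); the cut points between
    the reported ranges are configurable.
    """
    if not 0.0 <= angle_deg <= 180.0:
        raise ValueError("orbital angle must lie in [0, 180] degrees")
    if angle_deg <= frontal_max:
        return "frontal-eyed"
    if angle_deg <= wide_max:
        return "wide-field"
    return "lateral-eyed"


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one grouping analysis."""

    grouping: str = "group"
    domains: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DOMAINS_DEFAULT)
    )
    n_permutations: int = 4999
    seed: int = 0
    statistic: str = "location-scale"  # or "location"

    def __post_init__(self) -> None:
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if self.statistic not in ("location-scale", "location"):
            raise ValueError("statistic must be 'location-scale' or 'location'")
        all_vars = [v for vs in self.domains.values() for v in vs]
        if len(all_vars) != len(set(all_vars)):
            raise ValueError("domains must partition the variables (no overlap)")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(v for vs in self.domains.values() for v in vs)


# ---------------------------------------------------------------------------
# permutation schemes


def _multiset_count(counts: Sequence[int]) -> int:
    n = sum(counts)
    total = math.factorial(n)
    for c in counts:
        total //= math.factorial(c)
    return total


def _distinct_arrangements(codes: np.ndarray, k: int) -> np.ndarray:
    """All distinct arrangements of the code multiset, one per row."""
    counts = np.bincount(codes, minlength=k).tolist()
    n = len(codes)
    rows: list[list[int]] = []
    row = [0] * n

    def rec(pos: int) -> None:
        if pos == n:
            rows.append(row.copy())
            return
        for g in range(k):
            if counts[g]:
                counts[g] -= 1
                row[pos] = g
                rec(pos + 1)
                counts[g] += 1

    rec(0)
    return np.asarray(rows, dtype=np.int64)


@dataclass
class PermutationScheme:
    """A synchronized set of group relabelings.

    ``matrix`` holds one code assignment per row (row ``obs_index`` is the
    observed labeling); all partial statistics built from the same scheme
    share these permutations — the NPC synchronization contract.
    """

    matrix: np.ndarray  # (M, n) group codes
    obs_index: int
    exhaustive: bool
    group_labels: tuple

    @property
    def n_perms(self) -> int:
        return self.matrix.shape[0]

    @property
    def codes(self) -> np.ndarray:
        return self.matrix[self.obs_index]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)


def build_scheme(
    groups,
    n_permutations: int = 4999,
    rng: np.random.Generator | int | None = None,
    force_monte_carlo: bool = False,
) -> PermutationScheme:
    """Build the permutation scheme for a vector of group labels.

    Enumerates all distinct relabelings when their number is at most the
    requested permutation count; otherwise samples ``n_permutations``
    uniform shuffles and prepends the observed labeling.
    """
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if np.any(counts < 1):
        raise ValueError("every group needs at least one observation")
    total = _multiset_count(counts.tolist())
    if total <= n_permutations and not force_monte_carlo:
        mat = _distinct_arrangements(codes, len(labels))
        obs = int(np.flatnonzero((mat == codes).all(axis=1))[0])
        return PermutationScheme(mat, obs, True, tuple(labels))
    rng = np.random.default_rng(rng)
    mat = np.tile(codes, (n_permutations + 1, 1))
    mat[1:] = rng.permuted(mat[1:], axis=1)
    return PermutationScheme(mat, 0, False, tuple(labels))


# ---------------------------------------------------------------------------
# statistics


def _location_scale_stats(
    values: np.ndarray, scheme: PermutationScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Between-group location and scale statistics for every permutation.

    Location: sum_j n_j (mean_j - grand_mean)^2.  Scale: the same quadratic
    form applied to the within-group mean absolute deviations, which is
    sensitive to group-specific dispersion (the sigma2_j of the model).
    """
    v = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(v)):
        raise ValueError("values must be finite")
    C = scheme.matrix
    n = len(v)
    grand = v.mean()
    t_loc = np.zeros(C.shape[0])
    means = []
    masks = []
    counts = []
    for g in range(scheme.n_groups):
        mask = C == g
        n_g = int(mask.sum(axis=1)[0])  # group sizes are permutation-invariant
        mean_g = (mask * v).sum(axis=1) / n_g
        t_loc += n_g * (mean_g - grand) ** 2
        means.append(mean_g)
        masks.append(mask)
        counts.append(n_g)
    mu_pos = np.zeros_like(C, dtype=float)
    for g in range(scheme.n_groups):
        mu_pos += means[g][:, None] * masks[g]
    absdev = np.abs(v[None, :] - mu_pos)
    disp = np.stack(
        [(masks[g] * absdev).sum(axis=1) / counts[g] for g in range(scheme.n_groups)]
    )  # (k, M)
    w = np.asarray(counts, dtype=float)
    grand_disp = (w[:, None] * disp).sum(axis=0) / n
    t_scale = (w[:, None] * (disp - grand_disp) ** 2).sum(axis=0)
    return t_loc, t_scale


def _attained_pvalues(stats: np.ndarray) -> np.ndarray:
    """Attained p-value of each permutation's statistic within the whole
    permutation distribution: ``p[b] = #{b': T[b'] >= T[b]} / M`` (ties
    counted, values in [1/M, 1])."""
    s = np.asarray(stats, dtype=float)
    order = np.sort(s)
    n_less = np.searchsorted(order, s, side="left")
    return (len(s) - n_less) / len(s)


def _fisher_stat(partials: Sequence[np.ndarray]) -> np.ndarray:
    """Fisher combining function on the attained partial p-values:
    ``T = -2 sum_v log p_v`` per permutation."""
    lengths = {len(p) for p in partials}
    if len(lengths) != 1:
        raise ValueError(
            "partial tests are not synchronized: differing permutation counts"
        )
    T = np.zeros(lengths.pop())
    for s in partials:
        T += -2.0 * np.log(_attained_pvalues(s))
    return T


def _pvalue(stats: np.ndarray, obs_index: int) -> float:
    return float((stats >= stats[obs_index]).mean())


def _variable_statistic(
    values: np.ndarray, scheme: PermutationScheme, statistic: str
) -> np.ndarray:
    """Per-permutation statistic of one variable (larger = more evidence)."""
    t_loc, t_scale = _location_scale_stats(values, scheme)
    if statistic == "location":
        return t_loc
    return _fisher_stat([t_loc, t_scale])


@dataclass
class PermutationTestResult:
    """Result of a univariate permutation test, retaining the per-permutation
    statistics so it can enter an NPC combination."""

    p_value: float
    statistics: np.ndarray
    scheme: PermutationScheme

    @property
    def exhaustive(self) -> bool:
        return self.scheme.exhaustive


def permutation_test(
    values,
    groups,
    n_permutations: int = 4999,
    seed: int | np.random.Generator | None = 0,
    statistic: str = "location-scale",
    force_monte_carlo: bool = False,
) -> PermutationTestResult:
    """Two-or-more-sample permutation test of one variable.

    The statistic combines a location partial (between-group sum of squared
    mean deviations) and a scale partial (between-group deviation of the
    within-group mean absolute deviations); ``statistic='location'``
    switches the scale partial off.  Deterministic given ``seed``; exact by
    enumeration when the number of distinct relabelings is at most
    ``n_permutations``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    scheme = build_scheme(groups, n_permutations, seed, force_monte_carlo)
    stats = _variable_statistic(values, scheme, statistic)
    return PermutationTestResult(_pvalue(stats, scheme.obs_index), stats, scheme)


def npc_fisher_combine(
    partials: Sequence[np.ndarray | PermutationTestResult],
    obs_index: int | None = None,
) -> tuple[float, np.ndarray]:
    """Combine synchronized partial tests with the Fisher function.

    ``partials`` are per-permutation statistic vectors (or univariate test
    results) that must all come from the same permutation scheme; the
    combined statistic per permutation is ``-2 sum_v log p~_v(b)`` with
    ``p~_v`` the attained partial p-values.  Returns the combined p-value
    and the combined per-permutation statistic (reusable in a further
    combination level).  Differing permutation counts mean the inputs were
    not synchronized and raise ``ValueError``.
    """
    arrays: list[np.ndarray] = []
    for p in partials:
        if isinstance(p, PermutationTestResult):
            if obs_index is None:
                obs_index = p.scheme.obs_index
            elif obs_index != p.scheme.obs_index:
                raise ValueError("partial tests are not synchronized")
            arrays.append(p.statistics)
        else:
            arrays.append(np.asarray(p, dtype=float))
    if not arrays:
        raise ValueError("nothing to combine")
    if obs_index is None:
        obs_index = 0
    T = _fisher_stat(arrays)
    return _pvalue(T, obs_index), T


# ---------------------------------------------------------------------------
# pairwise tests and Shaffer adjustment


def _integer_partitions(k: int):
    """Partitions of the integer k as non-increasing tuples."""

    def rec(rest: int, maxpart: int):
        if rest == 0:
            yield ()
            return
        for first in range(min(rest, maxpart), 0, -1):
            for tail in rec(rest - first, first):
                yield (first, *tail)

    return rec(k, k)


def possible_true_null_counts(k: int) -> list[int]:
    """Numbers of pairwise equality hypotheses that can hold simultaneously
    among k groups: partition the groups into equal-valued blocks; each
    block of size c contributes c(c-1)/2 true pairwise nulls."""
    return sorted({sum(c * (c - 1) // 2 for c in p) for p in _integer_partitions(k)})


def shaffer_multipliers(k: int) -> list[int]:
    """Step-down multipliers t_i for the sorted pairwise p-values: the
    maximum number of nulls that can still be simultaneously true after
    i-1 rejections, respecting the logical constraints of equalities."""
    m = k * (k - 1) // 2
    S = possible_true_null_counts(k)
    return [max(s for s in S if s <= m - i) for i in range(m)]


def shaffer_adjust(raw_p: Mapping | Sequence[float], k: int):
    """Shaffer step-down adjusted p-values for all k(k-1)/2 pairwise tests.

    ``adj_(i) = max(adj_(i-1), min(1, t_i * p_(i)))`` over the ascending
    raw p-values.  Accepts a mapping pair->p (returned in kind) or a
    sequence.  An incomplete pair set is an error.
    """
    m = k * (k - 1) // 2
    if isinstance(raw_p, Mapping):
        keys = list(raw_p.keys())
        vals = np.asarray([raw_p[key] for key in keys], dtype=float)
    else:
        keys = None
        vals = np.asarray(list(raw_p), dtype=float)
    if len(vals) != m:
        raise ValueError(f"expected {m} pairwise p-values for k={k}, got {len(vals)}")
    mult = shaffer_multipliers(k)
    order = np.argsort(vals, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, mult[rank] * vals[idx]))
        adj[idx] = running
    if keys is not None:
        return {key: float(a) for key, a in zip(keys, adj)}
    return adj


def pairwise_tests(
    values: np.ndarray,
    groups,
    n_permutations: int = 4999,
    seed: int | np.random.Generator | None = 0,
    statistic: str = "location-scale",
) -> dict[tuple, float]:
    """Raw pairwise p-values for one variable: for each group pair the
    permutations are constrained to relabeling only those two groups' rows
    (identical to running the two-sample test on the pair alone)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(seed)
    out: dict[tuple, float] = {}
    for a, b in itertools.combinations(labels, 2):
        sel = (groups == a) | (groups == b)
        res = permutation_test(
            values[sel], groups[sel], n_permutations, rng, statistic
        )
        out[(a, b)] = res.p_value
    return out


# ---------------------------------------------------------------------------
# full grouping analysis


@dataclass
class LayerResult:
    """All tests of one layer: per-variable partial p, per-domain combined
    p, global p, and pairwise raw/Shaffer-adjusted matrices per variable
    and per domain."""

    layer: str
    partial_p: dict[str, float]
    domain_p: dict[str, float]
    global_p: float
    pairwise_raw: dict[str, dict[tuple, float]]
    pairwise_adjusted: dict[str, dict[tuple, float]]


@dataclass
class StudyResult:
    grouping: str
    groups: tuple
    spec: ModelSpec
    layers: dict[str, LayerResult]

    def to_frame(self) -> pd.DataFrame:
        """Tidy results table: one row per (layer, level, name, comparison)."""
        var_domain = {
            v: d for d, vs in self.spec.domains.items() for v in vs
        }
        rows = []
        for layer, lr in self.layers.items():
            for var, p in lr.partial_p.items():
                rows.append(
                    (layer, "variable", var, var_domain.get(var, ""), "omnibus", p, np.nan)
                )
            for dom, p in lr.domain_p.items():
                rows.append((layer, "domain", dom, dom, "omnibus", p, np.nan))
            rows.append((layer, "global", "global", "", "omnibus", lr.global_p, np.nan))
            for name, praw in lr.pairwise_raw.items():
                padj = lr.pairwise_adjusted[name]
                dom = var_domain.get(name, name if name in self.spec.domains else "")
                level = "variable" if name in var_domain else "domain"
                for pair, p in praw.items():
                    rows.append(
                        (layer, level, name, dom, f"{pair[0]}|{pair[1]}", p, padj[pair])
                    )
        return pd.DataFrame(
            rows,
            columns=["layer", "level", "name", "domain", "comparison", "raw_p", "adjusted_p"],
        )


def _analyze_layer(
    layer: str,
    data: pd.DataFrame,
    groups: np.ndarray,
    spec: ModelSpec,
    rng: np.random.Generator,
) -> LayerResult:
    scheme = build_scheme(groups, spec.n_permutations, rng)
    var_stats: dict[str, np.ndarray] = {}
    partial_p: dict[str, float] = {}
    for var in spec.variables:
        s = _variable_statistic(data[var].to_numpy(), scheme, spec.statistic)
        var_stats[var] = s
        partial_p[var] = _pvalue(s, scheme.obs_index)
    domain_p: dict[str, float] = {}
    domain_stats: list[np.ndarray] = []
    for dom, vs in spec.domains.items():
        p, T = npc_fisher_combine([var_stats[v] for v in vs], scheme.obs_index)
        domain_p[dom] = p
        domain_stats.append(T)
    global_p, _ = npc_fisher_combine(domain_stats, scheme.obs_index)

    k = scheme.n_groups
    pairwise_raw: dict[str, dict[tuple, float]] = {
        name: {} for name in (*spec.variables, *spec.domains)
    }
    for a, b in itertools.combinations(scheme.group_labels, 2):
        sel = (groups == a) | (groups == b)
        sub = data.loc[sel]
        pair_scheme = build_scheme(groups[sel], spec.n_permutations, rng)
        pair_stats: dict[str, np.ndarray] = {}
        for var in spec.variables:
            s = _variable_statistic(sub[var].to_numpy(), pair_scheme, spec.statistic)
            pair_stats[var] = s
            pairwise_raw[var][(a, b)] = _pvalue(s, pair_scheme.obs_index)
        for dom, vs in spec.domains.items():
            p, _ = npc_fisher_combine([pair_stats[v] for v in vs], pair_scheme.obs_index)
            pairwise_raw[dom][(a, b)] = p
    pairwise_adjusted = {
        name: shaffer_adjust(praw, k) for name, praw in pairwise_raw.items()
    }
    return LayerResult(layer, partial_p, domain_p, global_p, pairwise_raw, pairwise_adjusted)


def run_grouping_analysis(
    medians: pd.DataFrame,
    metadata: pd.DataFrame,
    spec: ModelSpec,
) -> StudyResult:
    """Run the full analysis for one grouping variable.

    ``medians`` holds one row per specimen × layer with the per-layer
    median descriptors (columns named as in ``spec.domains``); ``metadata``
    maps ``specimen_id`` to the grouping column ``spec.grouping``.  Layers
    are separate test families: permutations never pool rows across
    layers.  Rows are canonicalized by specimen id, so input row order is
    irrelevant; all randomness derives from ``spec.seed``.
    """
    if spec.grouping not in metadata.columns:
        raise ValueError(f"metadata lacks grouping column {spec.grouping!r}")
    meta = metadata.set_index("specimen_id")[spec.grouping]
    if meta.isna().any():
        raise ValueError("missing group labels in metadata")
    df = medians.copy()
    missing = set(df["specimen_id"]) - set(meta.index)
    if missing:
        raise ValueError(f"specimens without metadata: {sorted(missing)}")
    df["_group"] = df["specimen_id"].map(meta).astype(str)
    ss = np.random.SeedSequence(spec.seed)
    layers = sorted(df["layer"].unique())
    children = ss.spawn(len(layers))
    results: dict[str, LayerResult] = {}
    all_groups = tuple(sorted(df["_group"].unique()))
    for layer, child in zip(layers, children):
        sub = df[df["layer"] == layer].sort_values("specimen_id").reset_index(drop=True)
        groups = sub["_group"].to_numpy()
        present = set(groups)
        if present != set(all_groups):
            raise ValueError(
                f"layer {layer}: groups {sorted(set(all_groups) - present)} have no "
                f"observations"
            )
        bad = [v for v in spec.variables if sub[v].isna().any()]
        if bad:
            raise ValueError(f"layer {layer}: missing values in {bad}")
        results[layer] = _analyze_layer(
            layer, sub, groups, spec, np.random.default_rng(child)
        )
    return StudyResult(spec.grouping, all_groups, spec, results)
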