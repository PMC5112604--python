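"""Mixed-level orthogonal screening designs for multi-factor elicitation experiments.

The screening experiment this package targets varies 12 two-level factors
(macronutrients, elicitors, light), one three-level factor (cytokinin
identity) and one four-level factor (auxin identity) over 96 runs arranged as
an orthogonal array: every factor is balanced and every pair of factors is
level-combination balanced, so all main effects are mutually orthogonal.

The array is constructed from the full factorial over the multi-level factors
and a set of two-level "carrier" columns; the four-level factor is decomposed
into two pseudo-bits, and the remaining two-level factors are accommodated on
+/-1 product (interaction) columns of the base, chosen greedily to minimise
the number of main-effect/two-factor-interaction confounding triples
(diagnosed by canonical correlations, see :func:`alias_triples`).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.power import TTestIndPower

__all__ = [
    "FactorSpec",
    "Design",
    "AliasReport",
    "InfeasibleDesignError",
    "tobacco_screen_factors",
    "build_design",
    "check_orthogonality",
    "alias_triples",
    "power_two_level",
    "ofat_run_count",
    "indicator_matrix",
    "write_design",
    "read_design",
]

#: squared canonical correlations >= 1 - this tolerance count as aliased
CANCORR_TOL = 1e-8


class InfeasibleDesignError(ValueError):
    """Requested run count cannot satisfy the balance invariants."""


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor.

    Parameters
    ----------
    name : str
        Factor name (used as column header and indicator name).
    levels : tuple of str
        Ordered level labels. Two labels make a two-level factor (the second
        label is the "high" level); three or four labels make a multi-level
        factor whose labels are typically substance names.
    low_value, high_value : str, optional
        Physical quantities with units (e.g. ``"0.1 mM"``); documentation
        only, never used in computation.
    """

    name: str
    levels: tuple[str, ...]
    low_value: str | None = None
    high_value: str | None = None

    def __post_init__(self) -> None:
        if not 2 <= len(self.levels) <= 4:
            raise ValueError(
                f"factor {self.name!r}: needs 2-4 levels, got {len(self.levels)}"
            )
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"factor {self.name!r}: duplicate level labels")

    @property
    def kind(self) -> str:
        return "two_level" if len(self.levels) == 2 else "multi_level"

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class Design:
    """A runs x factors assignment of level labels plus run-order metadata.

    ``assignment`` rows are in standard (construction) order; ``run_order``
    is the seed-reproducible randomised execution order (a permutation of
    0..runs-1 giving, for each execution slot, the standard-order row run
    there). Analyses are order-agnostic.
    """

    factors: list[FactorSpec]
    assignment: pd.DataFrame
    run_order: np.ndarray
    seed: int

    @property
    def runs(self) -> int:
        return len(self.assignment)

    def factor(self, name: str) -> FactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def in_run_order(self) -> pd.DataFrame:
        return self.assignment.iloc[self.run_order]


@dataclass
class AliasReport:
    """Confounding triples of a design.

    ``triples`` lists, for every unordered factor triple with at least one
    squared canonical correlation of 1 between a main-effect contrast space
    and the interaction space of the other two factors, the triple and the
    count of such correlations (up to 3 directed checks per triple).
    """

    triples: list[tuple[tuple[str, str, str], int]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(c for _, c in self.triples)


# ---------------------------------------------------------------------------
# default factor specification of the tobacco cell-culture screen
# ---------------------------------------------------------------------------

def tobacco_screen_factors() -> list[FactorSpec]:
    """The 14-factor specification of the tobacco suspension-culture screen.

    Twelve two-level (low/high) factors: the macronutrients KNO3, NH4NO3,
    CaCl2, KH2PO4 and MgSO4; the elicitors MeJA, salicylic acid, GA3,
    ethephon, cyclanilide and ABA; and light. One four-level factor selects
    which auxin is supplied (IAA, IBA, NAA or 2,4-D) and one three-level
    factor which cytokinin (kinetin, DHZ or BAP) -- exactly one hormone of
    each family is present in every run.
    """
    two = ["KNO3", "NH4NO3", "CaCl2", "KH2PO4", "MgSO4", "MeJA",
           "salicylic_acid", "GA3", "ethephon", "cyclanilide", "ABA", "light"]
    specs = [FactorSpec(n, ("low", "high")) for n in two]
    specs.append(FactorSpec("auxin", ("IAA", "IBA", "NAA", "2,4-D")))
    specs.append(FactorSpec("cytokinin", ("kinetin", "DHZ", "BAP")))
    return specs


# ---------------------------------------------------------------------------
# contrast machinery (shared by alias_triples and the greedy constructor)
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(labels: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the centered indicator space of one factor."""
    levels = pd.unique(labels)
    ind = np.column_stack([(labels == lv).astype(float) for lv in levels])
    ind -= ind.mean(axis=0)
    q, r = np.linalg.qr(ind)
    keep = np.abs(np.diag(r)) > 1e-9
    return q[:, keep]


def _interaction_basis(qa: np.ndarray, qb: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the span of columnwise contrast products."""
    prods = np.einsum("ni,nj->nij", qa, qb).reshape(qa.shape[0], -1)
    u, s, _ = np.linalg.svd(prods, full_matrices=False)
    return u[:, s > 1e-9 * max(1.0, s[0] if s.size else 1.0)]


def _n_aliased(qa: np.ndarray, q_int: np.ndarray, tol: float = CANCORR_TOL) -> int:
    if qa.size == 0 or q_int.size == 0:
        return 0
    sv = np.linalg.svd(qa.T @ q_int, compute_uv=False)
    return int(np.sum(sv**2 >= 1.0 - tol))


def _triple_count(q: dict[str, np.ndarray], a: str, b: str, c: str) -> int:
    """Directed alias checks within an unordered triple {a, b, c}."""
    n = 0
    for main, f1, f2 in ((a, b, c), (b, a, c), (c, a, b)):
        n += _n_aliased(q[main], _interaction_basis(q[f1], q[f2]))
    return n


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _candidate_columns(multi: list[FactorSpec], n_carriers: int,
                       base_levels: dict[str, np.ndarray]
                       ) -> list[tuple[tuple[str, ...], np.ndarray]]:
    """Balanced +/-1 product columns available for two-level factors.

    Bits: two pseudo-bits per four-level factor plus the carriers. Subsets
    lying entirely within one four-level factor's pseudo-bits alias that
    factor's main effect and are excluded. Candidates are ordered by product
    order then name, so greedy tie-breaks are deterministic.
    """
    bits: dict[str, np.ndarray] = {}
    own: dict[str, str] = {}
    for f in multi:
        if f.n_levels == 4:
            idx = np.array([f.levels.index(v) for v in base_levels[f.name]])
            bits[f.name + ":b1"] = np.where(idx % 2 == 0, -1.0, 1.0)
            bits[f.name + ":b2"] = np.where(idx // 2 == 0, -1.0, 1.0)
            own[f.name + ":b1"] = f.name
            own[f.name + ":b2"] = f.name
    for j in range(n_carriers):
        bits[f"c{j + 1}"] = base_levels[f"c{j + 1}"].astype(float)

    names = sorted(bits, key=lambda s: (own.get(s, ""), s))
    cands = []
    for r in range(1, len(names) + 1):
        for subset in itertools.combinations(names, r):
            owners = {own[s] for s in subset if s in own}
            if owners and all(s in own for s in subset) and len(owners) == 1:
                continue  # aliases a four-level main effect
            col = np.prod([bits[s] for s in subset], axis=0)
            cands.append((subset, col))
    cands.sort(key=lambda t: (len(t[0]), t[0]))
    return cands


def build_design(factor_specs: list[FactorSpec], runs: int, seed: int) -> Design:
    """Construct a balanced mixed-level orthogonal array.

    The base is the full factorial over the multi-level factors and
    ``log2(runs / prod(multi levels))`` two-level carriers; two-level factors
    are assigned greedily to +/-1 product columns of the base, minimising the
    number of newly created confounding triples (ties broken toward
    lower-order products). Both balance invariants are verified before the
    design is returned.

    Raises
    ------
    InfeasibleDesignError
        If ``runs`` violates a divisibility constraint or the candidate pool
        cannot host all two-level factors.
    """
    names = [f.name for f in factor_specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate factor names")
    for fa, fb in itertools.combinations(factor_specs, 2):
        cell = fa.n_levels * fb.n_levels
        if runs % cell:
            raise InfeasibleDesignError(
                f"runs={runs} not divisible by |{fa.name}| x |{fb.name}| = {cell}"
            )
    multi = [f for f in factor_specs if f.kind == "multi_level"]
    two = [f for f in factor_specs if f.kind == "two_level"]
    base_cells = math.prod(f.n_levels for f in multi) if multi else 1
    if runs % base_cells:
        raise InfeasibleDesignError(
            f"runs={runs} not divisible by the multi-level full factorial "
            f"size {base_cells}"
        )
    q, n_carriers = runs // base_cells, 0
    while q % 2 == 0:
        q //= 2
        n_carriers += 1
    if q != 1:
        raise InfeasibleDesignError(
            f"runs={runs} is not (multi-level factorial size {base_cells}) x "
            f"(a power of 2); violated divisibility by 2 at remainder {q}"
        )

    # base full factorial, standard order
    grids = [list(f.levels) for f in multi] + [[-1, 1]] * n_carriers
    cols = [f.name for f in multi] + [f"c{j + 1}" for j in range(n_carriers)]
    frame = pd.DataFrame(list(itertools.product(*grids)), columns=cols)
    base_levels = {c: frame[c].to_numpy() for c in cols}

    cands = _candidate_columns(multi, n_carriers, base_levels)
    if len(cands) < len(two):
        raise InfeasibleDesignError(
            f"only {len(cands)} balanced columns available for "
            f"{len(two)} two-level factors at runs={runs}"
        )

    assignment = pd.DataFrame(
        {f.name: frame[f.name].to_numpy() for f in multi}, index=frame.index
    )
    contrasts: dict[str, np.ndarray] = {
        f.name: _orthonormal_contrasts(assignment[f.name].to_numpy())
        for f in multi
    }
    used: set[tuple[str, ...]] = set()
    for f in two:
        best: tuple[int, int] | None = None
        best_subset, best_col = None, None
        for rank, (subset, col) in enumerate(cands):
            if subset in used:
                continue
            qn = col.reshape(-1, 1) / math.sqrt(runs)
            added = 0
            existing = list(contrasts)
            for i, j in itertools.combinations(range(len(existing)), 2):
                trial = dict(contrasts)
                trial[f.name] = qn
                added += _triple_count(trial, f.name, existing[i], existing[j])
            key = (added, rank)
            if best is None or key < best:
                best, best_subset, best_col = key, subset, col
        assert best_subset is not None
        used.add(best_subset)
        labels = np.where(best_col > 0, f.levels[1], f.levels[0])
        assignment[f.name] = labels
        contrasts[f.name] = best_col.reshape(-1, 1) / math.sqrt(runs)

    assignment = assignment[[f.name for f in factor_specs]].astype(str)
    assignment.index = pd.RangeIndex(1, runs + 1, name="run_id")
    rng = np.random.default_rng(seed)
    design = Design(
        factors=list(factor_specs),
        assignment=assignment,
        run_order=rng.permutation(runs),
        seed=seed,
    )
    report = check_orthogonality(design)
    if not report["pass"]:
        raise InfeasibleDesignError(
            f"constructed design failed balance checks: {report['violations']}"
        )
    return design


def check_orthogonality(design: Design) -> dict:
    """Exact balance diagnostics.

    Returns a dict with ``pass``, per-factor level counts, per-pair
    contingency tables, and the list of violating factors/pairs. Pass
    requires every factor's levels to appear ``runs/k`` times and every
    pair's level combinations ``runs/(ka*kb)`` times (the orthogonal-array
    property).
    """
    A = design.assignment
    runs = design.runs
    factor_counts, pair_tables, violations = {}, {}, []
    for f in design.factors:
        counts = A[f.name].value_counts()
        factor_counts[f.name] = counts
        expect = runs / f.n_levels
        if len(counts) != f.n_levels or not (counts == expect).all():
            violations.append((f.name,))
    for fa, fb in itertools.combinations(design.factors, 2):
        tab = pd.crosstab(A[fa.name], A[fb.name])
        pair_tables[(fa.name, fb.name)] = tab
        expect = runs / (fa.n_levels * fb.n_levels)
        if tab.shape != (fa.n_levels, fb.n_levels) or not (tab == expect).all().all():
            violations.append((fa.name, fb.name))
    return {
        "pass": not violations,
        "factor_counts": factor_counts,
        "pair_tables": pair_tables,
        "violations": violations,
    }


def alias_triples(design: Design, tol: float = CANCORR_TOL) -> AliasReport:
    """Count main-effect / two-factor-interaction confounding per factor triple.

    For every unordered triple {A, B, C}, canonical correlations are computed
    between each factor's centered main-effect contrast space and the span of
    the pairwise interaction contrasts (columnwise products of the other two
    factors' centered contrasts); a squared canonical correlation >= 1 - tol
    counts as complete confounding. Rank-deficient interaction matrices are
    handled by projecting onto their column space.
    """
    q = {
        f.name: _orthonormal_contrasts(design.assignment[f.name].to_numpy())
        for f in design.factors
    }
    out = []
    for a, b, c in itertools.combinations([f.name for f in design.factors], 3):
        n = 0
        for main, f1, f2 in ((a, b, c), (b, a, c), (c, a, b)):
            n += _n_aliased(q[main], _interaction_basis(q[f1], q[f2]), tol)
        if n:
            out.append(((a, b, c), n))
    return AliasReport(triples=out)


def power_two_level(runs: int, effect_size_sd: float, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t-test for a balanced two-level factor.

    ``runs/2`` observations per level, pooled variance, df = runs - 2,
    standardized mean difference ``effect_size_sd``; evaluated via the
    noncentral t distribution. At effect 0 the power equals ``alpha``.
    """
    if runs < 4 or runs % 2:
        raise ValueError(f"runs must be even and >= 4, got {runs}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if effect_size_sd < 0:
        raise ValueError("effect size must be non-negative")
    if effect_size_sd == 0:
        return alpha
    return float(
        TTestIndPower().power(
            effect_size=effect_size_sd, nobs1=runs // 2, alpha=alpha,
            ratio=1.0, alternative="two-sided",
        )
    )


def ofat_run_count(factor_specs: list[FactorSpec], replicates: int) -> int:
    """Runs needed by one-factor-at-a-time screening with replication.

    One reference condition plus, for each factor, its remaining levels
    varied one at a time, all replicated: ``(1 + sum(k_f - 1)) * replicates``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    return (1 + sum(f.n_levels - 1 for f in factor_specs)) * replicates


def indicator_matrix(design: Design) -> pd.DataFrame:
    """0/1 response columns, one model per column.

    Two-level factors contribute one column (1 = high level); each level of a
    multi-level factor contributes its own presence column (the hormones are
    modelled one-vs-rest, so a k-level factor's k columns sum to all-ones).
    """
    cols: dict[str, np.ndarray] = {}
    for f in design.factors:
        labels = design.assignment[f.name].to_numpy()
        if f.kind == "two_level":
            cols[f.name] = (labels == f.levels[1]).astype(int)
        else:
            for lv in f.levels:
                cols[lv] = (labels == lv).astype(int)
    return pd.DataFrame(cols, index=design.assignment.index)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_design(design: Design, path: str | Path) -> None:
    """CSV (run_id + one column per factor) with a sidecar ``.json`` carrying
    factor metadata, seed and run order."""
    path = Path(path)
    design.assignment.to_csv(path)
    meta = {
        "seed": design.seed,
        "run_order": design.run_order.tolist(),
        "factors": [
            {"name": f.name, "levels": list(f.levels),
             "low_value": f.low_value, "high_value": f.high_value}
            for f in design.factors
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_design(path: str | Path) -> Design:
    path = Path(path)
    assignment = pd.read_csv(path, index_col="run_id", dtype=str)
    assignment.index = assignment.index.astype(int)
    meta = json.loads(path.with_suffix(".json").read_text())
    factors = [
        FactorSpec(d["name"], tuple(d["levels"]), d.get("low_value"),
                   d.get("high_value"))
        for d in meta["factors"]
    ]
    return Design(
        factors=factors,
        assignment=assignment,
        run_order=np.asarray(meta["run_order"], dtype=int),
        seed=int(meta["seed"]),
    )
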