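"""Deterministic count-profile scenarios and index sweeps.

Each scenario builds synthetic count vectors with a known richness,
evenness and sampling-effort structure, then sweeps one or more indices
over a parameter grid, yielding a tidy table.  The canonical grids probe:

1. Shannon vs. richness under increasing dominance of the first behavior
   (dominance factor k in {1, 2, 10, 100}).
2. The three Simpson variants on one shared equal-abundance grid.
3. Simpson's D under the same dominance design as (1).
4. Simpson's D vs. per-behavior effort m in {1, 2, 3, 4, 5, 10, 100}
   (count sensitivity, in contrast to Shannon's scale invariance).
5. Menhinick and 6. Margalef over that same effort grid (both decrease
   with effort at fixed richness).
7. Chao1 at fixed richness 10 as more categories are reduced to
   singletons.

Every scenario is a deterministic construction — no random number
generation anywhere — so re-running a sweep yields byte-identical tables.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import indices as _idx
from .data import CountVector

__all__ = [
    "Scenario",
    "make_counts",
    "run_sweep",
    "figure_sweep",
    "export_figure_table",
    "FIGURE_IDS",
]

SCENARIO_KINDS = ("equal", "dominant_first", "effort_sweep", "singleton_sweep")

#: Default richness grid and per-behavior effort grid.
DEFAULT_S_RANGE = tuple(range(1, 11))
DEFAULT_EFFORT_LEVELS = (1, 2, 3, 4, 5, 10, 100)

FIGURE_IDS = tuple(range(1, 8))


@dataclass(frozen=True)
class Scenario:
    """A parameterized synthetic count-profile generator.

    Parameters
    ----------
    kind
        ``equal``: S categories, each with count m (== dominant_first
        with k=1).  ``dominant_first``: first category k*m, the rest m.
        ``effort_sweep``: equal counts, m swept over ``effort_levels``.
        ``singleton_sweep``: ``n_singletons`` categories at count 1, the
        remainder at base count m (m >= 2).
    s_range
        Richness values to sweep.
    m
        Per-behavior base count.
    k
        Dominance multiplier on the first behavior.
    effort_levels
        m values for the effort sweep.
    n_singletons
        Number of singleton categories (singleton_sweep only); swept
        0..S-1 by :func:`run_sweep` when left at None.
    """

    kind: str
    s_range: tuple[int, ...] = DEFAULT_S_RANGE
    m: int = 10
    k: int = 1
    effort_levels: tuple[int, ...] = DEFAULT_EFFORT_LEVELS
    n_singletons: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"kind must be one of {SCENARIO_KINDS}, got {self.kind!r}")
        object.__setattr__(self, "s_range", tuple(int(s) for s in self.s_range))
        object.__setattr__(self, "effort_levels", tuple(int(m) for m in self.effort_levels))
        if not self.s_range or any(s < 1 for s in self.s_range):
            raise ValueError("s_range must be non-empty positive integers")
        if self.m < 1:
            raise ValueError("base count m must be >= 1")
        if self.k < 1:
            raise ValueError("dominance factor k must be >= 1")
        if any(m < 1 for m in self.effort_levels):
            raise ValueError("effort levels must be >= 1")
        if self.kind == "equal" and self.k != 1:
            raise ValueError("equal scenario requires k=1")
        if self.kind == "singleton_sweep":
            if self.m < 2:
                raise ValueError("singleton_sweep base count m must be >= 2")
            if self.n_singletons is not None:
                if self.n_singletons < 0 or any(self.n_singletons > s for s in self.s_range):
                    raise ValueError("n_singletons must satisfy 0 <= n_singletons <= S")


def make_counts(
    sc: Scenario,
    S: int,
    *,
    m: int | None = None,
    n_singletons: int | None = None,
) -> CountVector:
    """Build the count vector for one grid cell of a scenario.

    Labels are ``b1..bS`` in dominance order (the dominant behavior, if
    any, is ``b1``), giving stable, diffable tables.  ``m`` and
    ``n_singletons`` override the scenario defaults for effort and
    singleton sweeps.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    base = sc.m if m is None else int(m)
    if base < 1:
        raise ValueError("base count m must be >= 1")
    labels = [f"b{i}" for i in range(1, S + 1)]
    if sc.kind in ("equal", "effort_sweep"):
        counts = {lab: base for lab in labels}
    elif sc.kind == "dominant_first":
        counts = {lab: base for lab in labels}
        counts[labels[0]] = sc.k * base
    elif sc.kind == "singleton_sweep":
        ns = sc.n_singletons if n_singletons is None else int(n_singletons)
        if ns is None:
            raise ValueError("singleton_sweep needs n_singletons")
        if not 0 <= ns <= S:
            raise ValueError(f"n_singletons must satisfy 0 <= n_singletons <= S, got {ns} for S={S}")
        if base < 2:
            raise ValueError("singleton_sweep base count m must be >= 2")
        counts = {lab: (1 if i < ns else base) for i, lab in enumerate(labels)}
    else:  # pragma: no cover - guarded by Scenario.__post_init__
        raise ValueError(f"unknown scenario kind {sc.kind!r}")
    return CountVector(counts)


_INDEX_FUNCS = {
    "richness": _idx.richness,
    "shannon": _idx.shannon,
    "simpson_d": _idx.simpson_d,
    "simpson_diversity": _idx.simpson_diversity,
    "simpson_reciprocal": _idx.simpson_reciprocal,
    "menhinick": _idx.menhinick,
    "margalef": _idx.margalef,
    "chao1": _idx.chao1,
}


def _cells(sc: Scenario) -> Iterable[tuple[int, int, int | None]]:
    """Yield (S, m, n_singletons) for every grid cell of a scenario."""
    if sc.kind in ("equal", "dominant_first"):
        for s in sc.s_range:
            yield s, sc.m, None
    elif sc.kind == "effort_sweep":
        for s in sc.s_range:
            for m in sc.effort_levels:
                yield s, m, None
    else:  # singleton_sweep
        for s in sc.s_range:
            sweep = range(0, s) if sc.n_singletons is None else (sc.n_singletons,)
            for ns in sweep:
                yield s, sc.m, ns


def run_sweep(sc: Scenario, index_names: Sequence[str]) -> pd.DataFrame:
    """Sweep indices over a scenario grid into a tidy table.

    One row per (grid cell, index), with columns
    ``kind, S, m, k, n_singletons, N, index, value, note``; undefined
    values appear as NaN with the reason in ``note``.
    """
    if not index_names:
        raise ValueError("index roster must be non-empty")
    unknown = [n for n in index_names if n not in _INDEX_FUNCS]
    if unknown:
        raise ValueError(f"unknown index names {unknown}; choose from {sorted(_INDEX_FUNCS)}")
    rows = []
    for s, m, ns in _cells(sc):
        cv = make_counts(sc, s, m=m, n_singletons=ns)
        for name in index_names:
            res = _INDEX_FUNCS[name](cv)
            rows.append(
                {
                    "kind": sc.kind,
                    "S": s,
                    "m": m,
                    "k": sc.k if sc.kind == "dominant_first" else 1,
                    "n_singletons": ns,
                    "N": cv.N,
                    "index": name,
                    "value": res.value,
                    "note": "; ".join(res.notes),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Canonical figure grids
# --------------------------------------------------------------------------

# (indices, scenario factory list); the dominance designs never state the
# base count m — Shannon is m-invariant, Simpson is not, so m=10 is a
# documented package default.
_FIGURES = {
    1: (["shannon"], [Scenario("dominant_first", k=k) for k in (1, 2, 10, 100)]),
    2: (["simpson_d", "simpson_diversity", "simpson_reciprocal"], [Scenario("equal")]),
    3: (["simpson_d"], [Scenario("dominant_first", k=k) for k in (1, 2, 10, 100)]),
    4: (["simpson_d"], [Scenario("effort_sweep")]),
    5: (["menhinick"], [Scenario("effort_sweep")]),
    6: (["margalef"], [Scenario("effort_sweep")]),
    7: (["chao1"], [Scenario("singleton_sweep", s_range=(10,), m=5)]),
}


def figure_sweep(figure: int) -> pd.DataFrame:
    """Recreate the tidy table behind one of the canonical figures (1-7)."""
    if figure not in _FIGURES:
        raise ValueError(f"figure must be in {FIGURE_IDS}, got {figure}")
    index_names, scenarios = _FIGURES[figure]
    return pd.concat(
        [run_sweep(sc, index_names) for sc in scenarios], ignore_index=True
    )


def _figure_axes(figure: int) -> tuple[str, str]:
    """(x column, series column) for each canonical figure."""
    return {
        1: ("S", "k"),
        2: ("S", "index"),
        3: ("S", "k"),
        4: ("S", "m"),
        5: ("S", "m"),
        6: ("S", "m"),
        7: ("n_singletons", "index"),
    }[figure]


def export_figure_table(
    result: pd.DataFrame,
    figure: int,
    path: str | Path,
    *,
    plot_path: str | Path | None = None,
) -> Path:
    """Write a figure's sweep table to CSV, optionally rendering a plot.

    The table must cover the figure's full parameter grid; missing cells
    are reported in the error.  Returns the CSV path written.
    """
    if figure not in _FIGURES:
        raise ValueError(f"figure must be in {FIGURE_IDS}, got {figure}")
    if result is None or result.empty:
        raise ValueError("empty sweep result: nothing to export")
    expected = figure_sweep(figure)
    xcol, series = _figure_axes(figure)
    want = set(map(tuple, expected[[xcol, series, "index"]].itertuples(index=False)))
    have = set(map(tuple, result[[xcol, series, "index"]].itertuples(index=False)))
    missing = sorted(want - have)
    if missing:
        raise ValueError(
            f"incomplete grid for figure {figure}: missing ({xcol}, {series}, index) "
            f"cells {missing}"
        )
    path = Path(path)
    result.to_csv(path, index=False)
    if plot_path is not None:
        _render_plot(result, figure, xcol, series, Path(plot_path))
    return path


def _render_plot(result: pd.DataFrame, figure: int, xcol: str, series: str, plot_path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for key, grp in result.groupby(series):
        grp = grp.sort_values(xcol)
        ax.plot(grp[xcol], grp["value"], marker="o", label=f"{series}={key}")
    ax.set_xlabel(xcol)
    ax.set_ylabel("index value")
    ax.set_title(f"figure {figure}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(plot_path, dpi=150)
    plt.close(fig)
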