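"""Behavioral diversity indices on count vectors.

Implemented indices and their conventions:

==================  =====================================================
richness            S, the number of behavior categories observed
shannon             H' = -sum_i p_i ln p_i  (natural log; 0*ln 0 := 0)
simpson_d           D  = sum_i n_i(n_i - 1) / (N(N - 1))   (two scans
                    drawn without replacement share a behavior;
                    1 = lowest diversity)
simpson_diversity   1 - D
simpson_reciprocal  1 / D
menhinick           R1 = S / sqrt(N)
margalef            R2 = (S - 1) / ln N
chao1               Sobs + F1(F1 - 1) / (2(F2 + 1))  (bias-corrected;
                    classic F1^2 / (2 F2) behind an option)
bvi                 Behavioral Variety Index, (Ob / Ex) * 100
==================  =====================================================

Edge cases where a formula is undefined (e.g. Simpson with fewer than two
observations, Margalef with N <= 1) return an :class:`IndexResult` whose
``value`` is None and whose ``notes`` say why, rather than raising — batch
sweeps over parameter grids must complete even when some cells are
degenerate.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

from .data import CountVector, Ethogram, as_count_vector

__all__ = [
    "INDEX_NAMES",
    "IndexResult",
    "BVIInput",
    "richness",
    "shannon",
    "simpson_d",
    "simpson_diversity",
    "simpson_reciprocal",
    "menhinick",
    "margalef",
    "chao1",
    "bvi",
    "bvi_from_sets",
    "compute_all",
]

#: Roster of index names, in reporting order.
INDEX_NAMES = (
    "richness",
    "shannon",
    "simpson_d",
    "simpson_diversity",
    "simpson_reciprocal",
    "menhinick",
    "margalef",
    "chao1",
    "bvi",
)

_PROPORTION_TOL = 1e-9


@dataclass(frozen=True)
class IndexResult:
    """A named index value plus the input summary it was computed from.

    ``value`` is None when the index is undefined for the input, in which
    case ``notes`` carries a machine-readable reason (e.g.
    ``"undefined: N<2"``).  ``inputs_summary`` is the (S, N, F1, F2)
    snapshot of the count vector, or None for indices that do not consume
    one (BVI, proportion-based Shannon).
    """

    index_name: str
    value: float | None
    inputs_summary: tuple[int, int, int, int] | None = None
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.index_name not in INDEX_NAMES:
            raise ValueError(f"unknown index name {self.index_name!r}")
        if self.value is None and not self.notes:
            raise ValueError("undefined results must carry an explanatory note")

    @property
    def is_defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class BVIInput:
    """Observed (Ob) and expected (Ex) repertoire sizes for the BVI."""

    observed: int
    expected: int

    def __post_init__(self) -> None:
        if self.expected < 1:
            raise ValueError("expected repertoire size Ex must be >= 1")
        if self.observed < 0:
            raise ValueError("observed repertoire size Ob must be >= 0")


def _result(name: str, value: float | None, cv: CountVector | None, *notes: str) -> IndexResult:
    summary = cv.summary() if cv is not None else None
    return IndexResult(name, value, summary, tuple(notes))


def richness(cv) -> IndexResult:
    """Behavioral richness: the number of behavior categories observed.

    The simplest diversity measure; blind to evenness and to sampling
    effort.  An empty count vector has richness 0.
    """
    cv = as_count_vector(cv)
    return _result("richness", float(cv.S), cv)


def shannon(counts, *, proportions: bool = False) -> IndexResult:
    """Shannon–Wiener index H' = -sum_i p_i ln p_i (natural log).

    Sensitive to both richness and evenness; invariant to total effort
    because it runs on the proportion of observations per behavior.
    Ranges from 0 (a single behavior) to ln S (all S behaviors equally
    frequent).

    Parameters
    ----------
    counts
        A CountVector / mapping of integer counts, or — with
        ``proportions=True`` — a mapping or sequence of proportions
        summing to 1 within 1e-9 (supports duration-based p_i).
    """
    if proportions:
        p_vals = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
        if any(p < 0 for p in p_vals):
            raise ValueError("proportions must be non-negative")
        total = sum(p_vals)
        if abs(total - 1.0) > _PROPORTION_TOL:
            raise ValueError(f"proportions must sum to 1 (got {total!r})")
        h = -sum(p * math.log(p) for p in p_vals if p > 0) + 0.0  # avoid -0.0
        return IndexResult("shannon", h, None, ("input: proportions",))
    cv = as_count_vector(counts)
    if cv.N == 0:
        return _result("shannon", None, cv, "undefined: N=0")
    h = -sum(p * math.log(p) for p in cv.proportions().values()) + 0.0  # avoid -0.0
    return _result("shannon", h, cv)


def simpson_d(cv) -> IndexResult:
    """Simpson's index D = sum_i n_i(n_i - 1) / (N(N - 1)).

    The probability that two observations drawn without replacement are
    of the same behavior; 1 is the lowest diversity, 0 the highest.
    Runs on raw counts, not proportions, so it is sensitive to the total
    number of observations.  Undefined for N < 2 (no pair of scans to
    compare).
    """
    cv = as_count_vector(cv)
    n_total = cv.N
    if n_total < 2:
        return _result("simpson_d", None, cv, "undefined: insufficient observations (N<2)")
    d = sum(n * (n - 1) for n in cv.observed_counts().values()) / (n_total * (n_total - 1))
    return _result("simpson_d", d, cv)


def simpson_diversity(cv) -> IndexResult:
    """Simpson's index of diversity, 1 - D; 1 = highest diversity."""
    base = simpson_d(cv)
    if not base.is_defined:
        return IndexResult("simpson_diversity", None, base.inputs_summary, base.notes)
    return IndexResult("simpson_diversity", 1.0 - base.value, base.inputs_summary)


def simpson_reciprocal(cv) -> IndexResult:
    """Simpson's Reciprocal index, 1 / D; lowest value 1, no upper limit."""
    base = simpson_d(cv)
    if not base.is_defined:
        return IndexResult("simpson_reciprocal", None, base.inputs_summary, base.notes)
    if base.value == 0:
        return IndexResult(
            "simpson_reciprocal", None, base.inputs_summary, ("undefined: reciprocal diverges (D=0)",)
        )
    return IndexResult("simpson_reciprocal", 1.0 / base.value, base.inputs_summary)


def menhinick(cv) -> IndexResult:
    """Menhinick's index R1 = S / sqrt(N).

    Richness standardised by effort; insensitive to evenness.  A value of
    1 means S equals the square root of N (e.g. 2 behaviors in 4
    observations).  Undefined for N = 0.
    """
    cv = as_count_vector(cv)
    if cv.N == 0:
        return _result("menhinick", None, cv, "undefined: N=0")
    return _result("menhinick", cv.S / math.sqrt(cv.N), cv)


def margalef(cv) -> IndexResult:
    """Margalef's index R2 = (S - 1) / ln N.

    Like Menhinick, an effort-corrected richness measure blind to
    evenness; 0 when a single behavior is seen.  Undefined for N <= 1
    (ln 1 = 0).
    """
    cv = as_count_vector(cv)
    if cv.N <= 1:
        return _result("margalef", None, cv, "undefined: N<=1 (ln N vanishes)")
    return _result("margalef", (cv.S - 1) / math.log(cv.N), cv)


def chao1(cv, *, bias_corrected: bool = True) -> IndexResult:
    """Chao1 estimator of the true number of behavior categories.

    Estimates how many categories remain unobserved from the prevalence
    of rarely seen ones: ``Sobs + F1(F1-1)/(2(F2+1))`` (bias-corrected,
    default; always defined) or the classic ``Sobs + F1^2/(2 F2)``
    (undefined when F2 = 0 with F1 > 0).  Equals observed richness
    exactly when singletons are absent, and never falls below it.
    """
    cv = as_count_vector(cv)
    if cv.N == 0:
        return _result("chao1", None, cv, "undefined: no observations")
    s_obs, f1, f2 = cv.S, cv.F1, cv.F2
    if bias_corrected:
        value = s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
        return _result("chao1", value, cv)
    if f1 == 0:
        return _result("chao1", float(s_obs), cv, "variant: classic")
    if f2 == 0:
        return _result("chao1", None, cv, "undefined: classic variant with F2=0", "variant: classic")
    return _result("chao1", s_obs + f1 * f1 / (2 * f2), cv, "variant: classic")


def bvi(inp: BVIInput | None = None, *, observed: int | None = None, expected: int | None = None) -> IndexResult:
    """Behavioral Variety Index, BVI = (Ob / Ex) * 100.

    The percentage of the expected (wild-type) behavioral repertoire of
    ``Ex`` categories actually observed; low values indicate poorer
    behavioral diversity.  Ob > Ex is allowed (captive animals can show
    behaviors absent from the wild ethogram) but flagged.
    """
    if inp is None:
        if observed is None or expected is None:
            raise TypeError("bvi needs a BVIInput or observed= and expected=")
        inp = BVIInput(observed, expected)
    notes: list[str] = []
    if inp.observed > inp.expected:
        notes.append("Ob exceeds Ex: behaviors observed beyond the expected repertoire")
    return IndexResult("bvi", 100.0 * inp.observed / inp.expected, None, tuple(notes))


def bvi_from_sets(observed_labels: Iterable[str], expected_labels: Iterable[str]) -> IndexResult:
    """BVI from label sets: Ob counts expected categories seen at least once.

    Observed labels outside the expected repertoire do not count toward
    Ob (the index measures expression of the wild-type repertoire); they
    are reported in the result notes.
    """
    observed = set(observed_labels)
    expected = set(expected_labels)
    if not expected:
        raise ValueError("expected repertoire must be non-empty")
    extras = sorted(observed - expected)
    res = bvi(observed=len(observed & expected), expected=len(expected))
    notes = res.notes
    if extras:
        notes = notes + (f"outside expected repertoire: {','.join(extras)}",)
    return IndexResult("bvi", res.value, None, notes)


def compute_all(
    cv,
    ethogram: Ethogram | None = None,
    *,
    chao1_bias_corrected: bool = True,
) -> list[IndexResult]:
    """Compute the full index battery for one count vector.

    Returns one :class:`IndexResult` per index; BVI is included only when
    an ethogram with an expected repertoire is supplied.  Undefined
    indices are reported with notes, never dropped.
    """
    cv = as_count_vector(cv)
    results = [
        richness(cv),
        shannon(cv),
        simpson_d(cv),
        simpson_diversity(cv),
        simpson_reciprocal(cv),
        menhinick(cv),
        margalef(cv),
        chao1(cv, bias_corrected=chao1_bias_corrected),
    ]
    if ethogram is not None and ethogram.expected_categories is not None:
        results.append(bvi_from_sets(cv.observed_categories(), ethogram.expected_categories))
    return results
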