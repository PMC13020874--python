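"""Evolutionary-fate classification of paralog pairs.

Given per-(pre-species, post-species) Euclidean distances between each
entity (paralog A, paralog B, paralog total T) and the pre-duplication
expression profile, each family is assigned one of four categories:

``ANCESTRAL_PRESERVED``
    one paralog is closest to the pre-duplication profile (possibly
    tied with the total) while the other paralog sits significantly
    further away — the major paralog likely preserved the ancestral
    function, freeing the minor paralog to evolve under less constraint;
``SUBFUNCTIONALIZATION``
    the total is strictly closest in absolute distance AND in relative
    (composition) distance — ancestral expression was qualitatively
    partitioned across tissues;
``HYPOFUNCTIONALIZATION_DOSAGE_SHARING``
    the total is strictly closest in absolute distance but relative
    distances do not differ — each paralog's level dropped with the
    tissue pattern unchanged, so both are required for ancestral dosage;
``UNCLASSIFIED``
    any other pattern (no significant absolute differences, or
    conflicting absolute/relative winners).

Significance uses a paired sign-flip permutation test over the
(pre-species, post-species) pairs; this replaces a phylogenetic mixed
model with an assumption-light, fully deterministic backend (it does not
model the species tree — a hook accepts externally computed p-values).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = (
    "ANCESTRAL_PRESERVED",
    "SUBFUNCTIONALIZATION",
    "HYPOFUNCTIONALIZATION_DOSAGE_SHARING",
    "UNCLASSIFIED",
)

_EPS = 1e-12


@dataclass
class TestResult:
    """Paired sign-flip permutation test outcome."""

    statistic: float  # mean paired difference
    p_value: float
    n_pairs: int
    n_permutations: int
    seed: int | None
    exhaustive: bool = False


def paired_permutation_test(
    dx: np.ndarray,
    dy: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = 0,
) -> TestResult:
    """Two-sided sign-flip permutation test on paired differences.

    The statistic is the mean of ``dx - dy``. When ``2**n - 1 <= n_perm``
    the full set of sign patterns is enumerated (exact p-value); the
    Monte-Carlo p-value otherwise uses the add-one estimator
    ``p = (1 + #{|perm| >= |obs|}) / (1 + n_perm)``, which matches the
    exhaustive value when enumeration covers all non-identity patterns.
    Fewer than 3 pairs cannot reach significance; a sentinel p = 1 is
    returned with a warning.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    if dx.shape != dy.shape:
        raise ValueError("paired distance vectors must have equal length")
    diffs = dx - dy
    n = diffs.size
    if n < 3:
        logger.warning("fewer than 3 matched pairs; returning sentinel p = 1")
        return TestResult(
            statistic=float(diffs.mean()) if n else float("nan"),
            p_value=1.0, n_pairs=n, n_permutations=0, seed=seed,
        )
    obs = float(diffs.mean())
    if n <= 22 and 2**n - 1 <= n_perm:
        # exhaustive: every sign pattern except the identity, plus the
        # observed arrangement itself in numerator and denominator
        signs = np.array(
            [[1 if (k >> i) & 1 == 0 else -1 for i in range(n)] for k in range(1, 2**n)]
        )
        stats = signs @ diffs / n
        count = int((np.abs(stats) >= abs(obs) - _EPS).sum())
        return TestResult(
            statistic=obs,
            p_value=(1 + count) / (2**n),
            n_pairs=n,
            n_permutations=2**n - 1,
            seed=seed,
            exhaustive=True,
        )
    rng = np.random.default_rng(seed)
    signs = rng.choice(np.array([-1.0, 1.0]), size=(n_perm, n))
    stats = signs @ diffs / n
    count = int((np.abs(stats) >= abs(obs) - _EPS).sum())
    return TestResult(
        statistic=obs,
        p_value=(1 + count) / (1 + n_perm),
        n_pairs=n,
        n_permutations=n_perm,
        seed=seed,
    )


@dataclass
class FateCall:
    """Classification outcome for one paralog-pair family."""

    family: str
    category: str
    major_paralog: str | None
    mean_d_abs: dict[str, float]
    mean_d_rel: dict[str, float]
    p_abs: dict[str, float]  # keys "A|B", "A|T", "B|T"
    p_rel: dict[str, float]
    trace: list[str] = field(default_factory=list)

    def to_record(self) -> dict:
        rec = {"family": self.family, "category": self.category,
               "major_paralog": self.major_paralog}
        for e, v in self.mean_d_abs.items():
            rec[f"mean_d_abs_{e}"] = v
        for e, v in self.mean_d_rel.items():
            rec[f"mean_d_rel_{e}"] = v
        for k, v in self.p_abs.items():
            rec[f"p_abs_{k.replace('|', '_')}"] = v
        for k, v in self.p_rel.items():
            rec[f"p_rel_{k.replace('|', '_')}"] = v
        return rec


def _pairwise_tests(
    wide: pd.DataFrame, n_perm: int, rng: np.random.Generator,
    external: dict[str, float] | None,
) -> dict[str, float]:
    out = {}
    for a, b in combinations(("A", "B", "T"), 2):
        key = f"{a}|{b}"
        seed = int(rng.integers(0, 2**31 - 1))  # drawn unconditionally: keeps
        # the rng stream identical whether or not external p-values are given
        if external is not None and key in external:
            out[key] = float(external[key])
            continue
        # undefined distances (e.g. relative distance of an all-zero
        # paralog) drop pairwise; too few remaining pairs give p = 1
        sub = wide[[a, b]].dropna()
        res = paired_permutation_test(
            sub[a].to_numpy(), sub[b].to_numpy(), n_perm=n_perm, seed=seed
        )
        out[key] = res.p_value
    return out


def classify_fate(
    table: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int | None = 0,
    external_p_abs: dict[str, float] | None = None,
    external_p_rel: dict[str, float] | None = None,
) -> FateCall:
    """Classify one family's DistanceTable rows.

    ``table`` must hold the family's rows with columns ``family,
    pre_species, post_species, entity, d_abs, d_rel`` and all three
    entities present for each (pre, post) pair. ``external_p_*`` allow a
    tree-aware mixed model's p-values (keys "A|B", "A|T", "B|T") to
    replace the permutation backend.
    """
    families = table["family"].unique()
    if len(families) != 1:
        raise ValueError("classify_fate expects a single family's rows")
    family = str(families[0])
    missing = {"A", "B", "T"} - set(table["entity"])
    if missing:
        raise ValueError(f"family {family}: missing entity rows {sorted(missing)}")
    rng = np.random.default_rng(seed)
    trace: list[str] = []

    def widen(col: str) -> pd.DataFrame:
        wide = table.pivot_table(
            index=["pre_species", "post_species"], columns="entity", values=col,
            dropna=False,
        )
        for entity in ("A", "B", "T"):
            if entity not in wide.columns:
                wide[entity] = np.nan
        return wide

    wide_abs = widen("d_abs").dropna()
    wide_rel = widen("d_rel")
    mean_abs = {e: float(wide_abs[e].mean()) for e in ("A", "B", "T")}
    mean_rel = {e: float(wide_rel[e].mean()) for e in ("A", "B", "T")}
    p_abs = _pairwise_tests(wide_abs, n_perm, rng, external_p_abs)
    p_rel = _pairwise_tests(wide_rel, n_perm, rng, external_p_rel)

    order = sorted(mean_abs, key=mean_abs.get)
    trace.append(
        "absolute-distance ranking: "
        + " < ".join(f"{e}({mean_abs[e]:.3g})" for e in order)
    )

    def sig(p: dict[str, float], x: str, y: str) -> bool:
        key = f"{x}|{y}" if f"{x}|{y}" in p else f"{y}|{x}"
        return p[key] < alpha

    call = None
    # rule: one paralog is the (possibly T-tied) minimum and the other
    # paralog is significantly further from the pre-duplication profile
    # than both that paralog and the total
    p_min = "A" if mean_abs["A"] <= mean_abs["B"] else "B"
    q = "B" if p_min == "A" else "A"
    q_above_p = sig(p_abs, p_min, q) and mean_abs[q] > mean_abs[p_min]
    q_above_t = sig(p_abs, q, "T") and mean_abs[q] > mean_abs["T"]
    t_below_p = sig(p_abs, p_min, "T") and mean_abs["T"] < mean_abs[p_min]
    if q_above_p and q_above_t and not t_below_p:
        trace.append(
            f"paralog {p_min} is the minimum (tied with T or strictly lowest); "
            f"{q} significantly higher than both -> ANCESTRAL_PRESERVED"
        )
        call = FateCall(family, "ANCESTRAL_PRESERVED", p_min, mean_abs, mean_rel,
                        p_abs, p_rel, trace)
    elif (
        mean_abs["T"] < mean_abs["A"]
        and mean_abs["T"] < mean_abs["B"]
        and sig(p_abs, "A", "T")
        and sig(p_abs, "B", "T")
    ):
        trace.append(
            "total expression T strictly lowest in absolute distance; "
            "evaluating relative distances"
        )
        rel_sig_at = sig(p_rel, "A", "T") and mean_rel["T"] < mean_rel["A"]
        rel_sig_bt = sig(p_rel, "B", "T") and mean_rel["T"] < mean_rel["B"]
        rel_none = not (sig(p_rel, "A", "B") or sig(p_rel, "A", "T") or sig(p_rel, "B", "T"))
        if (
            mean_rel["T"] <= min(mean_rel["A"], mean_rel["B"])
            and rel_sig_at
            and rel_sig_bt
        ):
            trace.append(
                "T also significantly lowest in relative distance -> SUBFUNCTIONALIZATION"
            )
            call = FateCall(family, "SUBFUNCTIONALIZATION", None, mean_abs, mean_rel,
                            p_abs, p_rel, trace)
        elif rel_none:
            trace.append(
                "no significant relative-distance differences -> "
                "HYPOFUNCTIONALIZATION_DOSAGE_SHARING"
            )
            call = FateCall(family, "HYPOFUNCTIONALIZATION_DOSAGE_SHARING", None,
                            mean_abs, mean_rel, p_abs, p_rel, trace)
        else:
            trace.append("conflicting relative-distance pattern -> UNCLASSIFIED")
            call = FateCall(family, "UNCLASSIFIED", None, mean_abs, mean_rel,
                            p_abs, p_rel, trace)
    if call is None:
        trace.append("no decisive absolute-distance pattern -> UNCLASSIFIED")
        call = FateCall(family, "UNCLASSIFIED", None, mean_abs, mean_rel,
                        p_abs, p_rel, trace)
    return call


def classify_all(
    tables: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int | None = 0,
) -> tuple[list[FateCall], pd.DataFrame]:
    """Classify every family in a DistanceTable; returns calls + summary frame.

    Per-family permutation seeds derive deterministically from ``seed``
    and the family name, so results do not depend on iteration order.
    """
    calls = []
    for family, sub in tables.groupby("family", sort=True):
        fam_seed = None
        if seed is not None:
            fam_seed = int(
                np.random.SeedSequence(
                    [seed, zlib.crc32(str(family).encode())]
                ).generate_state(1)[0] % (2**31)
            )
        calls.append(classify_fate(sub, alpha=alpha, n_perm=n_perm, seed=fam_seed))
    summary = pd.DataFrame([c.to_record() for c in calls])
    return calls, summary
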