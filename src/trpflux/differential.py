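"""Differential comparison of steady states between two conditions.

Per-replicate steady-state fluxes and concentrations are compared with an
unpaired two-tailed t-test (Welch by default, classic pooled-variance
Student's as an option), summarised as mean ± SEM, fold change
(condition B over condition A), p-value and a significance code, and
checked against an expected direction pattern (the hypoxic rewiring of Trp
flux away from the kynurenine pathway toward tryptamine).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .steady_state import SteadyStateResult

__all__ = [
    "compare_conditions",
    "significance_code",
    "sign_pattern",
    "SignPatternReport",
    "DEFAULT_EXPECTATIONS",
]

log = logging.getLogger(__name__)

#: significance-code thresholds (code applies when p <= threshold)
SIG_LEVELS = [(0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*")]


def significance_code(p: float) -> str:
    """Star code for a p-value: ns, *, **, ***, **** at 0.05/0.01/0.001/0.0001."""
    if not np.isfinite(p):
        return "ns"
    for thr, code in SIG_LEVELS:
        if p <= thr:
            return code
    return "ns"


def _welch_and_student(a: np.ndarray, b: np.ndarray) -> tuple:
    """(p_welch, p_student, t_welch) with explicit zero-variance handling.

    With zero variance in both arms the t statistic is undefined; the
    comparison degenerates to an exact equality check: identical means give
    p = 1, different means p = 0 (infinitely many sigma apart).
    """
    sa, sb = np.std(a, ddof=1), np.std(b, ddof=1)
    eps = 1e-9 * max(1.0, abs(a.mean()), abs(b.mean()))
    if sa <= eps and sb <= eps:
        p = 1.0 if abs(a.mean() - b.mean()) <= eps else 0.0
        t = 0.0 if p == 1.0 else math.inf
        return p, p, t
    with warnings.catch_warnings():
        # scipy warns about precision loss on nearly identical samples;
        # such quantities are handled by the degenerate branch above
        warnings.simplefilter("ignore", RuntimeWarning)
        welch = stats.ttest_ind(b, a, equal_var=False)
        student = stats.ttest_ind(b, a, equal_var=True)
    return float(welch.pvalue), float(student.pvalue), float(welch.statistic)


def compare_conditions(
    results_A: list[SteadyStateResult],
    results_B: list[SteadyStateResult],
    test: str = "welch",
) -> pd.DataFrame:
    """Differential table of fluxes and concentrations, B versus A.

    Non-converged replicates are excluded with a warning; at least two
    converged replicates per condition are required.  Returns a DataFrame
    with one row per quantity (every reaction flux, every dynamic-species
    concentration) and columns ``quantity, kind, mean_A, mean_B, sem_A,
    sem_B, fold_change, p_value, p_value_student, p_value_bh,
    significance_code, direction``.
    """
    if test not in ("welch", "student"):
        raise ValueError(f"unknown test {test!r}")

    def usable(results, label):
        kept = [r for r in results if r.converged]
        dropped = len(results) - len(kept)
        if dropped:
            log.warning("condition %s: excluded %d non-converged replicate(s)", label, dropped)
        return kept

    res_a = usable(results_A, "A")
    res_b = usable(results_B, "B")
    if len(res_a) < 2 or len(res_b) < 2:
        raise ValueError(
            f"need >=2 converged replicates per condition, got {len(res_a)} and {len(res_b)}"
        )

    quantities = [("flux", rid) for rid in res_a[0].fluxes]
    # boundary species are clamped; report only quantities that can change
    conc_ids = [s for s in res_a[0].concentrations]
    quantities += [("concentration", sid) for sid in conc_ids]

    rows = []
    for kind, qid in quantities:
        pick = (lambda r: r.fluxes[qid]) if kind == "flux" else (lambda r: r.concentrations[qid])
        a = np.array([pick(r) for r in res_a], dtype=float)
        b = np.array([pick(r) for r in res_b], dtype=float)
        p_w, p_s, t_w = _welch_and_student(a, b)
        p = p_w if test == "welch" else p_s
        mean_a, mean_b = a.mean(), b.mean()
        fold = mean_b / mean_a if mean_a != 0 else math.inf if mean_b > 0 else math.nan
        code = significance_code(p)
        if code == "ns" or not np.isfinite(fold) or fold == 1.0:
            direction = "flat"
        else:
            direction = "down" if fold < 1.0 else "up"
        rows.append({
            "quantity": qid,
            "kind": kind,
            "mean_A": mean_a,
            "mean_B": mean_b,
            "sem_A": stats.sem(a) if len(a) > 1 else math.nan,
            "sem_B": stats.sem(b) if len(b) > 1 else math.nan,
            "fold_change": fold,
            "t_statistic": t_w,
            "p_value": p,
            "p_value_student": p_s,
            "significance_code": code,
            "direction": direction,
        })
    table = pd.DataFrame(rows)
    # supplementary Benjamini-Hochberg column; star codes stay per-quantity
    finite = np.isfinite(table["p_value"].to_numpy())
    bh = np.full(len(table), np.nan)
    if finite.any():
        bh[finite] = stats.false_discovery_control(table.loc[finite, "p_value"], method="bh")
    table["p_value_bh"] = bh
    return table


#: expected hypoxia-vs-normoxia directions: flux rerouting away from the
#: kynurenine pathway toward tryptamine.  TPH1, KynA and I3P are left
#: unconstrained on purpose.
DEFAULT_EXPECTATIONS = {
    ("flux", "R_LAT1"): "down",
    ("flux", "R_LAT2"): "down",
    ("flux", "R_TDO2"): "down",
    ("flux", "R_KAT"): "down",
    ("flux", "R_KYNU_a"): "down",
    ("flux", "R_KYNU_b"): "down",
    ("flux", "R_KMO"): "down",
    ("flux", "R_HAAO"): "down",
    ("flux", "R_QPRT"): "down",
    ("flux", "R_DDC_trp"): "up",
    ("flux", "R_INMT_1"): "up",
    ("flux", "R_INMT_2"): "up",
    ("concentration", "Kyn"): "down",
    ("concentration", "HAA3"): "down",
    ("concentration", "Quin"): "down",
    ("concentration", "Trypta"): "up",
}


@dataclass
class SignPatternReport:
    """Per-quantity direction check against an expectation set."""

    checks: pd.DataFrame  # quantity, kind, expected, observed, passed
    mismatches: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.mismatches

    @property
    def n_checked(self) -> int:
        return len(self.checks)

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "n_checked": self.n_checked,
            "mismatches": list(self.mismatches),
            "warnings": list(self.warnings),
            "checks": self.checks.to_dict("records"),
        }


def sign_pattern(
    table: pd.DataFrame,
    expectations: dict | None = None,
) -> SignPatternReport:
    """Check observed significant directions against expected ones.

    ``expectations`` maps ``(kind, quantity id) -> "up" | "down"``.  A
    quantity passes iff its observed direction (significant up/down, or
    flat) equals the expected one.  Quantities missing from the table are
    reported as warnings; an empty table passes vacuously with a warning.
    """
    expectations = DEFAULT_EXPECTATIONS if expectations is None else expectations
    warnings: list = []
    if table.empty:
        warnings.append("empty differential table: vacuous pass")
        return SignPatternReport(
            checks=pd.DataFrame(columns=["quantity", "kind", "expected", "observed", "passed"]),
            warnings=warnings,
        )
    indexed = table.set_index(["kind", "quantity"])
    rows, mismatches = [], []
    for (kind, qid), expected in expectations.items():
        if (kind, qid) not in indexed.index:
            warnings.append(f"expected quantity not in table: {kind} {qid}")
            continue
        observed = indexed.loc[(kind, qid), "direction"]
        ok = observed == expected
        if not ok:
            mismatches.append(f"{kind} {qid}: expected {expected}, observed {observed}")
        rows.append({"quantity": qid, "kind": kind, "expected": expected,
                     "observed": observed, "passed": ok})
    return SignPatternReport(checks=pd.DataFrame(rows), mismatches=mismatches, warnings=warnings)
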