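"""Greedy participant-deletion age matching and the demographics table.

The matcher removes one participant at a time — always the one whose
removal leaves the remaining groups with the highest rank-sum p-value for
the age difference — until that p-value exceeds the threshold (0.1 by
default). Ties are broken deterministically: prefer removing from the
larger group, then the lowest subject id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats_core import TestResult, chi_square_independence, wilcoxon_rank_sum

__all__ = ["MatchResult", "MatchingError", "greedy_age_match", "demographics_table"]


class MatchingError(RuntimeError):
    """Threshold unreachable before a group shrank to the minimum size."""

    def __init__(self, best_p: float, msg: str | None = None):
        super().__init__(msg or f"age matching failed; best attainable p = {best_p:.4g}")
        self.best_p = best_p


@dataclass(frozen=True)
class MatchResult:
    kept_a: tuple[str, ...]
    kept_b: tuple[str, ...]
    removed_ids: tuple[str, ...]
    final_p: float
    n_iterations: int


def _ages(records) -> dict[str, float]:
    return {r.subject_id: r.age for r in records}


def greedy_age_match(group_a, group_b, p_threshold: float = 0.1,
                     min_group_size: int = 3) -> MatchResult:
    """Age-match two groups by greedy single-participant deletion.

    At every iteration each remaining participant (from either group) is a
    removal candidate; the candidate whose removal maximizes the rank-sum p
    of the age difference is deleted. Stops as soon as p > ``p_threshold``.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    ages_a, ages_b = _ages(group_a), _ages(group_b)

    def current_p(a: dict, b: dict) -> float:
        return wilcoxon_rank_sum(list(a.values()), list(b.values())).p_value

    removed: list[str] = []
    iterations = 0
    p = current_p(ages_a, ages_b)
    best_seen = p
    while p <= p_threshold:
        if len(ages_a) <= min_group_size and len(ages_b) <= min_group_size:
            raise MatchingError(best_seen)
        candidates = []
        for pool, other, tag in ((ages_a, ages_b, "a"), (ages_b, ages_a, "b")):
            if len(pool) <= min_group_size:
                continue
            for sid in pool:
                trial = {k: v for k, v in pool.items() if k != sid}
                p_try = current_p(trial, other) if tag == "a" else current_p(other, trial)
                # tie-break: larger source group first, then lowest id
                candidates.append((p_try, -len(pool), sid, tag))
        if not candidates:
            raise MatchingError(best_seen)
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        p, _, sid, tag = candidates[0]
        (ages_a if tag == "a" else ages_b).pop(sid)
        removed.append(sid)
        iterations += 1
        best_seen = max(best_seen, p)
    return MatchResult(
        kept_a=tuple(ages_a), kept_b=tuple(ages_b),
        removed_ids=tuple(removed), final_p=float(p), n_iterations=iterations,
    )


# --- demographics ---------------------------------------------------------

def _summary(values) -> dict:
    v = np.asarray([x for x in values if x is not None], dtype=float)
    if v.size == 0:
        return {"n": 0, "mean": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan}
    return {"n": int(v.size), "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "min": float(v.min()), "max": float(v.max())}


def _count_table(records_by_group, attr, levels) -> np.ndarray:
    return np.array([[sum(1 for r in recs if getattr(r, attr) == lv) for lv in levels]
                     for recs in records_by_group.values()])


def demographics_table(records) -> pd.DataFrame:
    """Per-group demographic summaries with between-group tests.

    Continuous rows (age, head motion, ADOS) report n, mean, SD and range
    and a two-sided Wilcoxon rank-sum p; categorical rows (sex, handedness)
    report counts and a chi-square p. ADOS is summarized for the ASD group
    only and never tested (controls are not assessed).
    """
    groups: dict[str, list] = {}
    for r in records:
        groups.setdefault(r.group, []).append(r)
    if not groups:
        raise ValueError("no records")
    names = sorted(groups)
    rows = []

    def cont_row(label, getter, tested=True):
        stats = {g: _summary(getter(r) for r in groups[g]) for g in names}
        p = np.nan
        if tested and len(names) == 2:
            a = [getter(r) for r in groups[names[0]] if getter(r) is not None]
            b = [getter(r) for r in groups[names[1]] if getter(r) is not None]
            if a and b:
                p = wilcoxon_rank_sum(a, b).p_value
        row = {"variable": label, "test": "wilcoxon" if tested else "", "p": p}
        for g in names:
            s = stats[g]
            row[f"{g}_n"] = s["n"]
            row[f"{g}_summary"] = (f"{s['mean']:.2f} ± {s['sd']:.2f} "
                                   f"({s['min']:.2f}–{s['max']:.2f})"
                                   if s["n"] else "—")
        rows.append(row)

    def cat_row(label, attr, levels):
        p = np.nan
        tab = _count_table(groups, attr, levels)
        if len(names) == 2 and np.all(tab.sum(axis=0) >= 0):
            keep = tab.sum(axis=0) > 0
            try:
                p = chi_square_independence(tab[:, keep]).p_value
            except ValueError:
                p = np.nan
        row = {"variable": label, "test": "chi2", "p": p}
        for gi, g in enumerate(names):
            row[f"{g}_n"] = len(groups[g])
            row[f"{g}_summary"] = "/".join(f"{tab[gi, j]}{lv}" for j, lv in enumerate(levels))
        rows.append(row)

    cont_row("age_years", lambda r: r.age)
    cat_row("sex", "sex", ("M", "F"))
    cat_row("handedness", "handedness", ("R", "L", "M"))
    cont_row("head_motion_mm", lambda r: r.head_motion)
    has_ados = any(r.ados_total is not None for g in names for r in groups[g])
    if has_ados:
        # summary only for groups that carry scores; no between-group test
        cont_row("ados_total", lambda r: r.ados_total, tested=False)
        cont_row("ados_social", lambda r: r.ados_social, tested=False)
    return pd.DataFrame(rows)
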