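"""Independent oracles used to cross-check the implementation.

Everything here is deliberately written straight-line and self-contained:
the decision-tree oracle re-encodes the guideline thresholds and the
shipped default interval table as literal if/else logic, and the exact-test
oracles enumerate distributions by brute force. None of it imports the
engine, scheduler or statistics code it is used to check.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Optional


def decision_tree_oracle(
    cyst_size: float,
    mpd: Optional[float],
    nodule_size: Optional[float],
    nodule_enhancing: Optional[bool],
    wall_thickened: bool,
    abrupt_duct_change: bool,
    lymphadenopathy: bool,
    obstructive_jaundice: bool,
    ca19_9: Optional[float],
    growth_mm_per_2y: Optional[float],
    acute_pancreatitis: bool,
    new_onset_diabetes: bool,
    surgically_fit: bool,
    visit_number: int = 0,
) -> tuple[str, Optional[str], Optional[float]]:
    """Straight-line re-encoding of the stratification and interval table.

    Returns (action, modality, interval_months).
    """
    # --- high-risk stigmata ---
    hrs = False
    if mpd is not None and mpd >= 10.0:
        hrs = True
    if obstructive_jaundice:
        hrs = True
    if nodule_size is not None and nodule_enhancing is True and nodule_size >= 5.0:
        hrs = True
    if hrs:
        if surgically_fit:
            return ("surgery_referral", None, None)
        return ("eus_surveillance", "eus", 6.0)

    # --- worrisome features ---
    any_wf = False
    if cyst_size >= 30.0:
        any_wf = True
    if nodule_size is not None and not (nodule_enhancing is True and nodule_size >= 5.0):
        any_wf = True
    if wall_thickened:
        any_wf = True
    if mpd is not None and 5.0 <= mpd < 10.0:
        any_wf = True
    if abrupt_duct_change:
        any_wf = True
    if lymphadenopathy:
        any_wf = True
    if ca19_9 is not None and ca19_9 > 37.0:
        any_wf = True
    if growth_mm_per_2y is not None and growth_mm_per_2y > 5.0:
        any_wf = True
    if acute_pancreatitis:
        any_wf = True
    if new_onset_diabetes:
        any_wf = True
    if any_wf:
        return ("eus_surveillance", "eus", 6.0)

    # --- size bands (no WF/HRS) ---
    if cyst_size < 20.0:
        # MRI at 6 months, then every 18 months if stable
        if visit_number == 0:
            return ("imaging_surveillance", "mri_mrcp", 6.0)
        return ("imaging_surveillance", "mri_mrcp", 18.0)
    # 20-29 mm: every 6 months the first year, then every 12 months
    if visit_number <= 1:
        return ("imaging_surveillance", "mri_mrcp", 6.0)
    return ("imaging_surveillance", "mri_mrcp", 12.0)


def fisher_exact_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration over fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    pmf = {
        x: math.comb(r1, x) * math.comb(r2, c1 - x) / denom for x in range(lo, hi + 1)
    }
    observed = pmf[a]
    total = sum(p for p in pmf.values() if p <= observed * (1 + 1e-9))
    return min(total, 1.0)


def mann_whitney_exact_oracle(x: list[float], y: list[float]) -> float:
    """Two-sided exact Mann-Whitney p by exhaustive rank assignment.

    Assumes no ties. Enumerates every way the pooled ranks could be split
    between the groups and counts splits at least as extreme as observed.
    """
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n2 = len(x), len(y)
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    u_big = max(u_obs, n1 * n2 - u_obs)
    count = 0
    total = 0
    all_ranks = list(range(1, n1 + n2 + 1))
    for subset in combinations(all_ranks, n1):
        u = sum(subset) - n1 * (n1 + 1) / 2
        if u >= u_big - 1e-9 or u <= n1 * n2 - u_big + 1e-9:
            count += 1
        total += 1
    return min(count / total, 1.0)
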