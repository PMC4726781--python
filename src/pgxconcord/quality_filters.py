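"""Evaluability predicates.

Each predicate is a total function over a :class:`~pgxconcord.callset_model.GenotypeCall`
and a :class:`~pgxconcord.callset_model.FilterThresholds`.  Inequality
directions follow the published rules literally: exome calls with read
depth < 4 or genotype quality < 10 are "not evaluable" (so depth 4 / GQ 10
pass), amplicon truth calls need a depth of at least 10-fold (inclusive),
and panel calls need a call rate strictly greater than 85%.  Absent
evidence always fails the corresponding predicate.
"""

from __future__ import annotations

from .callset_model import FilterThresholds, GenotypeCall


def test_call_evaluable(call: GenotypeCall, thresholds: FilterThresholds) -> bool:
    """True iff a test (exome) call clears both the DP and GQ floors."""
    if call.depth is None or call.gq is None:
        return False
    return call.depth >= thresholds.test_dp_min and call.gq >= thresholds.test_gq_min


def in_tranche_cut(call: GenotypeCall, thresholds: FilterThresholds) -> bool:
    """True iff the call's VQSR tranche is inside the configured cut."""
    return call.tranche in thresholds.tranche_cut


def truth_call_confident(call: GenotypeCall, thresholds: FilterThresholds) -> bool:
    """True iff an amplicon truth call has sufficient approximate depth."""
    return call.depth is not None and call.depth >= thresholds.truth_dp_min


def panel_call_confident(call: GenotypeCall, thresholds: FilterThresholds) -> bool:
    """True iff a panel call's call rate strictly exceeds the floor."""
    return call.call_rate is not None and call.call_rate > thresholds.panel_call_rate_min
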