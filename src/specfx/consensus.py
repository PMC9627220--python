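"""Consensus intersection of the three screening methods and overlap reports.

Per endpoint, the consensus active-peak set is the exact three-way
intersection of the GRA, PLSR-VIP and BP-ANN/MIV selections (the Venn
step).  Cross-endpoint overlaps (all pairwise and the full intersection
over endpoints) identify constituents shared between effects.
"""

from __future__ import annotations

import hashlib
import itertools
import json

from .errors import SpecfxError


def intersect_per_effect(gra_set, plsr_set, miv_set, universe=None) -> set[str]:
    """Three-way intersection of per-method selections for one endpoint."""
    sets = [set(gra_set), set(plsr_set), set(miv_set)]
    if universe is not None:
        universe = set(universe)
        for name, s in zip(("GRA", "PLSR", "MIV"), sets):
            unknown = s - universe
            if unknown:
                raise SpecfxError(f"{name} selection references unknown peak ids: "
                                  f"{sorted(unknown)}")
    return sets[0] & sets[1] & sets[2]


def shared_across_effects(consensus_sets: dict[str, set]) -> dict:
    """All pairwise and the full cross-endpoint intersections.

    ``consensus_sets`` maps endpoint name -> consensus peak set.  Returns a
    JSON-ready dict with sorted member lists.
    """
    if len(consensus_sets) < 2:
        raise SpecfxError("need at least 2 endpoints to intersect across effects")
    endpoints = list(consensus_sets)
    pairwise = {}
    for a, b in itertools.combinations(endpoints, 2):
        pairwise[f"{a} & {b}"] = sorted(consensus_sets[a] & consensus_sets[b],
                                        key=_peak_key)
    full = set(consensus_sets[endpoints[0]])
    for ep in endpoints[1:]:
        full &= consensus_sets[ep]
    return {
        "pairwise": pairwise,
        "full_intersection": sorted(full, key=_peak_key),
        "per_endpoint_sizes": {ep: len(consensus_sets[ep]) for ep in endpoints},
    }


def intersect_endpoints(consensus_sets: dict[str, set], endpoints) -> set[str]:
    """Intersection of the consensus sets of an arbitrary endpoint subset."""
    endpoints = list(endpoints)
    if not endpoints:
        raise SpecfxError("endpoint list is empty")
    out = set(consensus_sets[endpoints[0]])
    for ep in endpoints[1:]:
        out &= consensus_sets[ep]
    return out


def _peak_key(pid: str):
    """Sort P-numbered ids numerically, anything else lexically."""
    if isinstance(pid, str) and pid.startswith("P") and pid[1:].isdigit():
        return (0, int(pid[1:]))
    return (1, str(pid))


def screening_report(method_sets: dict[str, dict[str, set]],
                     scores: dict[str, dict[str, dict]] | None = None,
                     provenance: dict | None = None,
                     require_complete: bool = True) -> dict:
    """Machine-readable screening report over all endpoints.

    ``method_sets`` maps endpoint -> {"gra": set, "plsr": set, "miv": set};
    missing methods are flagged (and the endpoint's consensus omitted) when
    ``require_complete`` is False, otherwise raise.  ``scores`` may carry
    the full per-method score vectors so threshold sensitivity can be
    re-derived without recomputation.  The output is deterministic: sets
    are sorted, and ``json.dumps(report, sort_keys=True)`` is byte-stable.
    """
    report: dict = {"endpoints": {}, "provenance": provenance or {}}
    consensus_sets: dict[str, set] = {}
    incomplete = []
    for ep, methods in method_sets.items():
        entry: dict = {"methods": {}}
        missing = [m for m in ("gra", "plsr", "miv") if m not in methods]
        for m, s in methods.items():
            entry["methods"][m] = sorted(set(s), key=_peak_key)
        if missing:
            entry["missing_methods"] = missing
            incomplete.append(ep)
        else:
            cons = intersect_per_effect(methods["gra"], methods["plsr"], methods["miv"])
            consensus_sets[ep] = cons
            entry["consensus"] = sorted(cons, key=_peak_key)
            entry["consensus_size"] = len(cons)
        if scores and ep in scores:
            entry["scores"] = scores[ep]
        report["endpoints"][ep] = entry
    if incomplete and require_complete:
        raise SpecfxError(f"incomplete screening stages for endpoint(s): {incomplete}")
    if incomplete:
        report["incomplete_endpoints"] = incomplete
    if len(consensus_sets) >= 2:
        report["overlaps"] = shared_across_effects(consensus_sets)
    payload = json.dumps(report, sort_keys=True).encode()
    report["provenance"]["content_sha1"] = hashlib.sha1(payload).hexdigest()
    return report


def report_json(report: dict) -> str:
    """Canonical (byte-stable) JSON serialization of a screening report."""
    return json.dumps(report, sort_keys=True, indent=2)
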