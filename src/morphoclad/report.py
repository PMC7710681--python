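"""End-to-end reproduction of the packaged analysis, and report rendering.

``reproduce()`` runs the whole pipeline on the packaged fixtures: polarity
resolution, synapomorphy grouping, conflict arbitration, cladogram
construction, parsimony verification (including the exact branch-and-bound
minimum), homoplasy indices, and validation of the diagnostic key.  The
result is a plain dict, renderable as Markdown or JSON.
"""

from __future__ import annotations

import json

from . import fixtures
from .argumentation import arbitrate, build_cladogram, group_by_synapomorphy
from .key import validate_key
from .matrix import apply_polarity_policy
from .parsimony import (
    consistency_index,
    parsimony_length,
    reconstruct,
    retention_index,
)
from .search import branch_and_bound
from .tree import rf_distance

__all__ = ["reproduce", "render_markdown", "render_json"]


def reproduce(
    policy: str = "as-argued",
    placement: str = "delay-changes",
    time_budget: float | None = 900.0,
    run_search: bool = True,
) -> dict:
    """Run the packaged matrix through argumentation and verification."""
    matrix = fixtures.laophontodes_matrix()
    reference = fixtures.reference_cladogram()
    resolved = apply_polarity_policy(matrix, policy)

    hypotheses, conflicts = group_by_synapomorphy(resolved)
    report = arbitrate(hypotheses, conflicts, resolved)
    tree = build_cladogram(report)

    recs = reconstruct(reference, resolved, placement)
    single_origin_ingroup = sorted(
        r.char_id for r in recs if r.char_id != 1 and r.origin_count == 1
    )
    convergent = sorted(r.char_id for r in recs if r.origin_count > 1)

    length = parsimony_length(tree, resolved)
    result = {
        "matrix": {
            "n_characters": matrix.n_characters,
            "n_taxa": matrix.n_taxa,
            "policy": policy,
        },
        "groups": {
            "accepted_clade_sizes": sorted(
                (len(h.taxa) for h in report.accepted_clades if len(h.taxa) < matrix.n_taxa),
                reverse=True,
            ),
            "accepted_clades": [
                {
                    "taxa": sorted(h.taxa),
                    "characters": sorted(h.supporting_chars),
                }
                for h in report.accepted_clades
            ],
            "autapomorphies": {
                t: sorted(ids) for t, ids in sorted(report.autapomorphies.items())
            },
            "convergences": {
                str(cid): [sorted(origin) for origin in origins]
                for cid, origins in sorted(report.convergences.items())
            },
        },
        "reconstruction": {
            "placement": placement,
            "convergent_characters": convergent,
            "n_single_origin_ingroup": len(single_origin_ingroup),
        },
        "tree": {
            "newick": tree.newick(),
            "reference_newick": reference.newick(),
            "rf_to_reference": rf_distance(tree, reference),
            "length": length,
            "reference_length": parsimony_length(reference, resolved),
            "consistency_index": consistency_index(tree, resolved),
            "retention_index": retention_index(tree, resolved),
        },
        "key": {},
    }

    if run_search:
        search = branch_and_bound(resolved, time_budget=time_budget)
        result["search"] = {
            "best_length": search.best_length,
            "n_best_trees": search.n_best,
            "exhausted": search.exhausted,
            "nodes_examined": search.nodes_examined,
            "tree_is_optimal": search.best_length == length,
        }

    key = fixtures.laophontodes_key()
    violations = validate_key(key)
    result["key"] = {
        "valid": not violations,
        "n_couplets": len(key.couplets),
        "n_taxa": len(key.taxa),
        "violations": [
            {"couplet": v.couplet, "kind": v.kind, "detail": v.detail}
            for v in violations
        ],
    }
    return result


def render_json(result: dict) -> str:
    return json.dumps(result, indent=2, sort_keys=True)


def render_markdown(result: dict) -> str:
    lines = ["# Cladistic analysis report", ""]
    m = result["matrix"]
    lines.append(
        f"Matrix: {m['n_characters']} characters x {m['n_taxa']} taxa "
        f"(polarity policy: {m['policy']})."
    )
    lines.append("")
    g = result["groups"]
    lines.append("## Accepted clades")
    for clade in g["accepted_clades"]:
        chars = ", ".join(map(str, clade["characters"]))
        lines.append(f"- {{{', '.join(clade['taxa'])}}} — characters {chars}")
    lines.append("")
    lines.append("## Autapomorphies")
    for taxon, ids in g["autapomorphies"].items():
        lines.append(f"- {taxon}: {', '.join(map(str, ids))}")
    lines.append("")
    lines.append("## Convergences")
    for cid, origins in g["convergences"].items():
        rendered = "; ".join("{" + ", ".join(o) + "}" for o in origins)
        lines.append(f"- character {cid}: independent origins at {rendered}")
    lines.append("")
    t = result["tree"]
    lines.append("## Tree")
    lines.append(f"- cladogram: `{t['newick']}`")
    lines.append(f"- RF distance to reference: {t['rf_to_reference']}")
    lines.append(
        f"- length {t['length']} steps; CI {t['consistency_index']:.4f}; "
        f"RI {t['retention_index']:.4f}"
    )
    if "search" in result:
        s = result["search"]
        status = "exact" if s["exhausted"] else "incumbent (budget expired)"
        lines.append(
            f"- branch-and-bound minimum: {s['best_length']} steps "
            f"({status}; {s['n_best_trees']} optimal trees)"
        )
    k = result["key"]
    lines.append("")
    lines.append("## Diagnostic key")
    verdict = "valid" if k["valid"] else "INVALID"
    lines.append(
        f"- {verdict}: {k['n_couplets']} couplets, {k['n_taxa']} terminal taxa"
    )
    for v in k["violations"]:
        lines.append(f"  - {v['kind']} at couplet {v['couplet']}: {v['detail']}")
    return "\n".join(lines) + "\n"
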