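"""A tie in the middle of a dendrogram, between clusters that already formed.

Ties are not confined to the first merge: here a 10-taxon synthetic matrix
(4 decimal digits) first resolves two pairs, then one taxon is exactly
equidistant (1.0459) from both pairs, which themselves sit 1.1112 apart.
The tie therefore involves three *clusters*; it yields exactly two binary
dendrograms, and the multidendrogram shows one 3-way node whose band spans
[1.0459, 1.1112].  Writes results/nested_tie_case.json.
"""

import json
from pathlib import Path

from tieclust import (
    count_binary_dendrograms,
    fixture_nested_tie,
    multidendrogram,
    to_multidendro_json,
    to_newick,
    upgma,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> dict:
    m = fixture_nested_tie()
    res = count_binary_dendrograms(m, keep_trees=True)
    md = multidendrogram(m)

    def bands(node):
        if not getattr(node, "children", ()):
            return []
        own = [node.band] if node.band and node.band[0] != node.band[1] else []
        return own + [b for c in node.children for b in bands(c)]

    tie_bands = bands(md.root)
    report = {
        "n_taxa": m.n,
        "precision_p": m.precision_p,
        "n_binary_dendrograms": res.count,
        "states_visited": res.states_visited,
        "binary_dendrograms": sorted(res.trees),
        "tie_bands": tie_bands,
        "upgma_newick_first_index": to_newick(upgma(m)[0]),
        "multidendrogram": json.loads(to_multidendro_json(md)),
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "nested_tie_case.json").write_text(json.dumps(report, indent=2))
    print(f"{m.n} taxa at {m.precision_p} decimal digits")
    print(f"distinct binary dendrograms: {res.count}")
    for b in tie_bands:
        print(f"tie band: [{b[0]}, {b[1]}]")
    return report


if __name__ == "__main__":
    main()
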