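"""The minimal tie: B equidistant from A and C.

With d(A,B) = d(B,C) = 1 and d(A,C) = 2, the first UPGMA merge is tied and
two different binary dendrograms exist; the variable-group multidendrogram
instead fuses all three at once with tie band [1, 2].  Writes
results/intro_example.json.
"""

import json
from pathlib import Path

from tieclust import (
    canonical_form,
    count_binary_dendrograms,
    fixture_intro_chain,
    has_ties,
    multidendrogram,
    to_multidendro_json,
    to_newick,
    upgma,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> dict:
    m = fixture_intro_chain()
    tree, records = upgma(m, tie_rule="first_index")
    res = count_binary_dendrograms(m, keep_trees=True)
    md = multidendrogram(m)
    report = {
        "matrix": {"labels": m.labels, "values": m.values.tolist()},
        "upgma_newick": to_newick(tree),
        "tie_steps": [
            {"step": r.step_index, "d_min": r.d_min, "tied_pairs": r.tied_pairs}
            for r in records
            if r.is_tie
        ],
        "has_ties": has_ties(records),
        "n_binary_dendrograms": res.count,
        "binary_dendrograms": sorted(res.trees),
        "multidendrogram": json.loads(to_multidendro_json(md)),
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "intro_example.json").write_text(json.dumps(report, indent=2))
    print(f"UPGMA (first_index): {to_newick(tree)}")
    print(f"tied steps: {sum(r.is_tie for r in records)} of {len(records)}")
    print(f"distinct binary dendrograms: {res.count}")
    for canon in sorted(res.trees):
        print(f"  {canon}")
    band = md.root.band
    print(
        f"multidendrogram: one {len(md.root.children)}-way node at height "
        f"{md.root.height}, tie band [{band[0]}, {band[1]}]"
    )
    assert canonical_form(tree) in res.trees
    return report


if __name__ == "__main__":
    main()
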