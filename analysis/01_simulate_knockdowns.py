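#!/usr/bin/env python
"""Generate the synthetic knockdown compendium and record its ground truth.

Writes the planted-structure digest (regulon sizes, pair overlaps,
multiplicity histogram, feature models) to results/ground_truth.json.
Pass --write-tables to also dump the full TSV tables under scratch/.
"""

import argparse
import json

from common import STUDY_SEED, results_dir, study_dataset


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=STUDY_SEED)
    ap.add_argument("--write-tables", action="store_true")
    args = ap.parse_args()

    ds = study_dataset(args.seed)
    digest = ds.truth.summary()
    out = results_dir() / "ground_truth.json"
    out.write_text(json.dumps(digest, indent=2))

    sizes = digest["regulon_sizes"]
    print(f"simulated {len(sizes)} RBP knockdowns x {sorted(ds.tables)} cell lines")
    print(f"regulon sizes {min(sizes.values())}-{max(sizes.values())} exons")
    hist = digest["multiplicity_histogram"]
    print(f"planted multiplicity reaches {max(int(k) for k in hist)} RBPs per exon")
    print(f"ground truth digest -> {out}")

    if args.write_tables:
        from spliceinterdep.simulate import write_dataset

        scratch = out.parent.parent / "scratch" / "simulated"
        scratch.mkdir(parents=True, exist_ok=True)
        write_dataset(ds, scratch)
        print(f"full tables -> {scratch}")


if __name__ == "__main__":
    main()
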