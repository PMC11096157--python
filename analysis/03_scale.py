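#!/usr/bin/env python
"""Vary the federation size at a fixed total data volume.

The same training set is re-partitioned into k = 2..10 IID clients and
FedAvg is run for each k (3 repeat seeds).  With a small-capacity tagger the
F1 should deteriorate as the same data is spread over more clients.
"""

import argparse
from pathlib import Path

from fedbionlp.experiments import ExperimentConfig, run_scale, write_results


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    cfg = ExperimentConfig(design="scale")
    table = run_scale(cfg, base_seed=args.seed)
    write_results(table, args.out, "scale")
    print(table[["k", "lenient", "strict"]].to_string(index=False))
    print(f"\ntotal training volume at every k: {table.attrs['total_volume']}")
    drop = (
        table.set_index("k").loc[2, "lenient_mean"]
        - table.set_index("k").loc[10, "lenient_mean"]
    )
    print(f"lenient F1 drop from k=2 to k=10: {drop:+.3f}")


if __name__ == "__main__":
    main()
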