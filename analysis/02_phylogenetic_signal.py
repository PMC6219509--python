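"""Test each trait (and the joint trait table) for phylogenetic signal.

Computes Abouheif's C_mean with 999 tip randomizations per trait, and the
multivariate Moran statistic for the three traits jointly. A significant
result motivates the eigenvector-corrected reanalysis in step 05.
Writes results/signal/signal_tests.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from traitspace.io import TRAITS, read_newick, read_trait_table, records_to_frame
from traitspace.phylo import (
    abouheif_proximity,
    test_signal,
    test_signal_multivariate,
)
from traitspace.pipeline import subset_phylogeny

BASE = Path(__file__).resolve().parents[1] / "results"
SEED = 20260923


def main() -> None:
    records = read_trait_table(BASE / "dataset" / "traits.csv")
    tree = read_newick(BASE / "dataset" / "tree.nwk")
    frame = records_to_frame(records)

    rows = []
    for trait in TRAITS:
        observed = frame[trait].dropna()
        prox = abouheif_proximity(subset_phylogeny(tree, list(observed.index)))
        values = np.log10(observed.loc[list(prox.tip_order)].to_numpy(float))
        res = test_signal(values, prox.W, n_perm=999, seed=SEED)
        rows.append({"trait": trait, "n": len(values),
                     "cmean": res.statistic, "p": res.p})
        print(f"{trait:<12} n={len(values):4d}  C_mean={res.statistic:6.3f}  "
              f"p={res.p:.3f}")

    complete = frame[list(TRAITS)].dropna()
    prox = abouheif_proximity(subset_phylogeny(tree, list(complete.index)))
    X = np.log10(complete.loc[list(prox.tip_order)].to_numpy(float))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    res = test_signal_multivariate(X, prox.W, n_perm=999, seed=SEED)
    rows.append({"trait": "multivariate", "n": len(X),
                 "cmean": res.statistic, "p": res.p})
    print(f"{'multivariate':<12} n={len(X):4d}  I={res.statistic:6.3f}  "
          f"p={res.p:.3f}")

    out = BASE / "signal"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "signal_tests.csv", index=False)
    print(f"wrote {out / 'signal_tests.csv'}")


if __name__ == "__main__":
    main()
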