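"""Gene-set enrichment of the selected probes and method-overlap report.

With synthetic data there is no real annotation, so probes map to symbols
through an identity annotation and the gene-set library is itself synthetic
(labelled as such): one term holding the planted DEG symbols plus noise,
and background terms drawn at random.  The enrichment table should rank the
planted term first with a vanishing hypergeometric p; the Venn-style report
compares the tensor selection against the per-tissue t-test selections.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from tensordx.baselines import tissue_matrix_from_tensor, ttest_select
from tensordx.enrichment import (GeneSetCollection, enrich, enrichment_table,
                                 map_probes_to_symbols, overlap_report)
from tensordx.geo_io import load_tensor

ROOT = Path(__file__).resolve().parent.parent


def synthetic_library(probe_ids, deg_ids, seed):
    """A synthetic GMT-style collection: one DEG-loaded term, 19 random ones."""
    rng = np.random.default_rng(seed)
    universe = set(probe_ids)
    sets = {"planted_deg_module": set(rng.choice(sorted(deg_ids), 150,
                                                 replace=False))
            | set(rng.choice(probe_ids, 50, replace=False))}
    for i in range(19):
        sets[f"random_term_{i:02d}"] = set(
            rng.choice(probe_ids, rng.integers(50, 300), replace=False))
    return GeneSetCollection(sets, universe)


def main(seed: int = 17) -> None:
    tensor = load_tensor(ROOT / "scratch" / "planted_tensor.npz")
    stats = pd.read_csv(ROOT / "scratch" / "planted_td_stats.tsv", sep="\t")
    selected = stats.loc[stats["selected"], "probe_id"].tolist()
    truth = pd.read_csv(ROOT / "scratch" / "simulated" / "planted" / "truth.tsv",
                        sep="\t")
    deg_ids = set(truth.loc[truth["is_deg"] == 1, "probe_id"])

    annotation = pd.DataFrame({"probe_id": tensor.probe_ids,
                               "symbol": tensor.probe_ids})
    symbols, map_report = map_probes_to_symbols(selected, annotation)
    collection = synthetic_library(tensor.probe_ids, deg_ids, seed)
    rows, run_report = enrich(symbols, collection)
    table = enrichment_table(rows)
    table.to_csv(ROOT / "results" / "05_enrichment.tsv", sep="\t", index=False)
    print(table.head(5).to_string(index=False))
    print(f"\nmapped {map_report['n_probes']} probes -> "
          f"{map_report['n_symbols']} symbols "
          f"({map_report['n_unmapped']} unmapped)")

    selections = {"td": set(selected)}
    for tissue in tensor.axis_labels["tissue"]:
        res = ttest_select(tissue_matrix_from_tensor(tensor, tissue))
        selections[f"ttest_{tissue}"] = res.selected_ids
    venn = overlap_report({k: selections[k]
                           for k in ("td", "ttest_adipose", "ttest_liver")})
    serializable = {
        "regions": {"+".join(sorted(k)) or "none": v
                    for k, v in venn["regions"].items()},
        "set_sizes": venn["set_sizes"], "union_size": venn["union_size"],
    }
    (ROOT / "results" / "05_overlaps.json").write_text(
        json.dumps(serializable, indent=2) + "\n")
    print("\nVenn regions (exclusive):")
    for k, v in sorted(serializable["regions"].items()):
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
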