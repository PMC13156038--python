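"""Stratified expression summaries of the receptor maps.

Means per anatomical stratum (7 cortical intrinsic networks, 7 subcortical
structures, hypothalamus), medians per structure class, and the hierarchical
clustering order of receptors used to sort expression heatmaps.

Writes results/stratified/.
"""

import json
from pathlib import Path

from peptidemaps import load_matrix, load_region_atlas, stratified_summary

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "stratified"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    atlas = load_region_atlas(ROOT / "sim" / "atlas.tsv")
    expr = load_matrix(ROOT / "qc" / "expression_normalized.tsv", atlas)

    summary = stratified_summary(expr, atlas)
    summary.stratum_means.to_csv(OUT / "stratum_means.tsv", sep="\t")
    summary.structure_medians.to_csv(OUT / "structure_medians.tsv", sep="\t")
    (OUT / "receptor_order.json").write_text(json.dumps(summary.ordering, indent=2))

    med = summary.structure_medians
    cortical = (med.loc["cortex"] > med.loc["subcortex"]).sum()
    print(f"strata summarized: {summary.stratum_means.shape[0]} strata x "
          f"{summary.stratum_means.shape[1]} receptors")
    print(f"{cortical} receptors with cortical median above subcortical median")
    print("heatmap order (first 5):", summary.ordering[:5])


if __name__ == "__main__":
    main()
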