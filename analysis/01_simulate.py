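"""Generate the synthetic study inputs.

Builds a 455-region whole-brain atlas (400 cortical parcels in 7 intrinsic
networks, 54 subcortical parcels in 7 structures, 1 hypothalamus region) and
the regional data every later stage consumes: 38 receptor-like expression
maps, a 6-donor expression stack with moderate inter-donor reliability, 16
PET-like neurotransmitter density maps, 125 term-like maps sharing one
planted latent dimension with the receptor maps, and a 2,000-gene background
pool with heterogeneous spatial autocorrelation.

Writes everything under results/sim/ as TSV plus a truth JSON.
"""

import json
from pathlib import Path

import numpy as np

from peptidemaps import RegionalMatrix, SAParams, pairwise_distances
from peptidemaps.datasets import load_pet_receptors, load_receptor_annotation
from peptidemaps.simulate import (
    GRFSampler,
    PlantedLatentTruth,
    atlas_diameter,
    make_atlas,
    make_donor_stack,
    make_gene_pool,
    make_planted_latent,
)

SEED = 2026
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    atlas = make_atlas(400, 54, True, seed=SEED)
    atlas.save(OUT / "atlas.tsv")
    dist = pairwise_distances(atlas)
    diam = atlas_diameter(atlas)
    print(f"atlas: {atlas.n_regions} regions, diameter {diam:.0f} mm")

    genes = list(load_receptor_annotation().table.gene)
    sampler = GRFSampler(dist, SAParams(corr_range=diam / 5))

    pet_info = load_pet_receptors()
    pet_names = list(pet_info["receptor"])
    pet_values = sampler.sample(rng, len(pet_names))
    pet = RegionalMatrix(atlas, pet_names, pet_values)
    pet.save(OUT / "pet_maps.tsv")

    # receptor maps share ~60% of their spatial variance with the
    # neurotransmitter maps, with metabotropic predictors weighted twice as
    # heavily as ionotropic ones; the two opioid genes load mostly on their
    # PET counterparts so gene-vs-PET correspondence is recoverable
    shared_var = 0.6
    class_weight = np.where(pet_info["receptor_class"] == "metabotropic", 2.0, 1.0)
    pet_std = (pet_values - pet_values.mean(axis=0)) / pet_values.std(axis=0)
    receptor_values = np.empty((atlas.n_regions, len(genes)))
    for j, gene in enumerate(genes):
        w = rng.random(len(pet_names)) * class_weight
        if gene == "OPRM1":
            w[pet_names.index("MOR")] += 5.0
        if gene == "OPRK1":
            w[pet_names.index("KOR")] += 5.0
        combo = pet_std @ w
        combo /= combo.std()
        private = sampler.sample(rng, 1)[:, 0]
        private /= private.std()
        receptor_values[:, j] = (
            np.sqrt(shared_var) * combo + np.sqrt(1 - shared_var) * private
        )
    receptor = RegionalMatrix(atlas, genes, receptor_values)
    receptor.save(OUT / "receptor_maps.tsv")

    donors = make_donor_stack(atlas, 6, len(genes), reliability=0.5, seed=SEED + 1)
    for d, donor in enumerate(donors):
        RegionalMatrix(atlas, genes, donor.values).save(OUT / f"donor_{d}.tsv")

    truth = PlantedLatentTruth(
        rng.standard_normal(len(genes)), rng.standard_normal(125), latent_share=0.8
    )
    terms_x, terms_y, _ = make_planted_latent(
        atlas, len(genes), 125, truth, seed=SEED + 2
    )
    terms_x.save(OUT / "receptor_maps_latent.tsv")
    term_cols = [f"term_{j:03d}" for j in range(125)]
    RegionalMatrix(atlas, term_cols, terms_y.values).save(OUT / "term_maps.tsv")

    pool, ranges = make_gene_pool(atlas, 2000, 5.0, diam / 2, seed=SEED + 3)
    pool.save(OUT / "gene_pool.tsv")

    (OUT / "truth.json").write_text(
        json.dumps(
            {
                "seed": SEED,
                "receptor_corr_range_mm": diam / 5,
                "receptor_pet_shared_variance": shared_var,
                "metabotropic_weight_ratio": 2.0,
                "donor_reliability": 0.5,
                "latent_share": 0.8,
                "latent_x_weights": truth.x_weights.tolist(),
                "latent_y_weights": truth.y_weights.tolist(),
                "pool_range_mm": [5.0, diam / 2],
                "pool_truth_ranges": ranges.tolist(),
            },
            indent=2,
        )
    )
    print(f"wrote {len(list(OUT.glob('*.tsv')))} tables to {OUT}")


if __name__ == "__main__":
    main()
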