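"""Generate the synthetic study cohort.

Draws a 29-strain pan-genome with core + rare-accessory architecture, ten
prey, one planted predation gene per prey (10 mm additive effect, carriage
1/3, 1 mm assay noise), plus COG-letter annotations from a fixed background
profile, and writes everything under results/data/.
"""

from pathlib import Path

from predgwas import default_config, simulate_cog_annotations, simulate_pangenome
from predgwas.io import (
    write_annotation_table,
    write_phenotype_table,
    write_roary_presence_absence,
)

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = default_config(SEED)
    dataset = simulate_pangenome(config)

    write_roary_presence_absence(dataset.matrix, OUT / "matrix.csv")
    write_phenotype_table(dataset.phenotypes, OUT / "phenotypes.tsv")
    with open(OUT / "truth.tsv", "w") as handle:
        handle.write("cluster_id\taffected_prey\teffect_mm\tcarriage_fraction\n")
        for gene in dataset.truth:
            handle.write(
                f"{gene.cluster_id}\t{','.join(gene.affected_prey)}\t"
                f"{gene.effect_mm:g}\t{gene.carriage_fraction:g}\n"
            )
    annotation, _ = simulate_cog_annotations(dataset.matrix.cluster_ids, seed=SEED + 1)
    write_annotation_table(annotation, OUT / "annotations.tsv")

    accessory = dataset.matrix.presence.loc[
        [c for c in dataset.matrix.cluster_ids if c.startswith("acc_")]
    ]
    rare = (accessory.mean(axis=1) < 1 / 6).mean()
    print(f"seed: {SEED}")
    print(
        f"cohort: {dataset.matrix.n_strains} strains, "
        f"{dataset.matrix.n_clusters} clusters "
        f"({config.n_core} core, {config.n_accessory} accessory, "
        f"{len(dataset.truth)} planted), {len(config.prey_ids)} prey"
    )
    print(f"accessory clusters carried by < 1/6 of strains: {rare:.0%}")
    print(f"wrote matrix, phenotypes, truth and annotations to {OUT}")


if __name__ == "__main__":
    main()
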