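"""Genome-subsampling saturation analysis and power-law forecasting.

Reruns the full screen on random strain subsets of increasing size,
re-binarizing phenotypes within each subset, fits the mean hit count to
hits(G) = a * G^b on the log-log scale, and inverts the published decay
(22601 * G^-1.4) to forecast how many genomes a candidate-list target
would require.
"""

from pathlib import Path

from predgwas import (
    PowerLawFit,
    evaluate_power_law,
    fit_power_law,
    predict_required_genomes,
    subsample_gene_counts,
)
from predgwas.io import read_phenotype_table, read_roary_presence_absence

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 43
GRID = [15, 18, 21, 24, 27, 29]
REPS = 20


def main() -> None:
    matrix = read_roary_presence_absence(ROOT / "data" / "matrix.csv")
    panel = read_phenotype_table(ROOT / "data" / "phenotypes.tsv")

    curve = subsample_gene_counts(matrix, panel, GRID, reps=REPS, seed=SEED)
    out = ROOT / "saturation"
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "curve.tsv", "w") as handle:
        handle.write("genomes\tmean_hits\treplicate_hits\n")
        for g, mean in zip(curve.genome_counts, curve.mean_hits):
            reps = ",".join(str(c) for c in curve.replicate_hits[g])
            handle.write(f"{g}\t{mean:.12g}\t{reps}\n")

    print(f"seed: {SEED} ({REPS} replicates per genome count)")
    print("Saturation curve (genomes -> mean unique hits):")
    for g, mean in zip(curve.genome_counts, curve.mean_hits):
        print(f"  {g:3d} -> {mean:.1f}")

    fit = fit_power_law(curve)
    print(
        f"Fitted decay: hits(G) = {fit.coefficient:.1f} * G^{fit.exponent:.3f} "
        f"(R^2 = {fit.r_squared:.3f} on the log-log scale)"
    )
    with open(out / "fit.tsv", "w") as handle:
        handle.write("coefficient\texponent\tr_squared\n")
        handle.write(f"{fit.coefficient:.12g}\t{fit.exponent:.12g}\t{fit.r_squared:.12g}\n")

    # forecasting with a steep decay fitted on a large, diverse cohort
    published = PowerLawFit(coefficient=22601.0, exponent=-1.4)
    print("\nForecasts from the decay 22601 * G^-1.4:")
    for target in (100.0, 10.0):
        g_star = predict_required_genomes(published, target)
        print(
            f"  <= {target:g} candidate genes requires {g_star} genomes "
            f"(predicted hits there: {evaluate_power_law(published, g_star):.1f})"
        )
    print(f"  predicted hits at 250 genomes: {evaluate_power_law(published, 250):.2f}")


if __name__ == "__main__":
    main()
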