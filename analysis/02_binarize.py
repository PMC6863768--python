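"""Binarize the graded predation phenotypes into tertile labels.

Ranks the 29 strains per prey by predation-zone diameter, labels the top
third superior and bottom third inferior (9/9/11 at this cohort size),
writes the Scoary-style traits table, and reports predatory breadth —
how many prey each strain dominates.
"""

from pathlib import Path

from predgwas import binarize_panel, predatory_breadth
from predgwas.io import read_phenotype_table, write_traits_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    panel = read_phenotype_table(ROOT / "data" / "phenotypes.tsv")
    labels = binarize_panel(panel)

    write_traits_table(labels, ROOT / "traits.csv")
    breadth = predatory_breadth(labels)
    breadth.to_csv(ROOT / "predatory_breadth.csv", index=False)

    for prey in labels.prey_ids:
        counts = labels.counts(prey)
        print(
            f"{prey}: {counts['superior']} superior / "
            f"{counts['inferior']} inferior / {counts['moderate']} moderate"
        )
    top = breadth.head(3)
    print("\nBroadest predators:")
    for _, row in top.iterrows():
        print(f"  {row.strain_id}: superior against {row.n_superior}/{row.n_prey} prey")
    print(f"\nwrote {ROOT / 'traits.csv'} and {ROOT / 'predatory_breadth.csv'}")


if __name__ == "__main__":
    main()
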