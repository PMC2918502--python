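"""Generate the synthetic museum study and write its interchange files.

Writes the tree (Newick), taxonomy, collection years, maculation scores and
the ground-truth record under results/data/.  The raw spectra themselves are
regenerated on demand by later scripts (they are seed-determined); a small
excerpt is written so the interchange format is visible on disk.
"""

import json

from common import outdir, parse_seed, study_dataset

from eggcolor import write_spectra_table
from eggcolor.phylo_signal import write_newick_tree


def main() -> None:
    seed = parse_seed(__doc__)
    ds, grid, meta = study_dataset(seed)
    out = outdir("data")

    write_newick_tree(ds.tree, out / "tree.nwk")
    ds.taxonomy.to_csv(out / "taxonomy.csv", index=False)
    ds.years.to_csv(out / "years.csv", index=False)
    ds.maculation.to_csv(out / "maculation.csv", index=False)
    write_spectra_table(ds.raw_spectra[:12], out / "spectra_excerpt.csv")
    truth = {
        k: v for k, v in ds.truth.items() if not k.endswith("_by_species")
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=float)

    n_species = ds.taxonomy["species"].nunique()
    print(f"generated study (seed={seed}): {n_species} species in "
          f"{ds.taxonomy['family'].nunique()} families, "
          f"{len(ds.raw_spectra)} replicate spectra")
    print(f"collection years {ds.years['collection_year'].min()}-"
          f"{ds.years['collection_year'].max()}; "
          f"lambda_true={truth['lambda_true']}, "
          f"variance fractions={truth['variance_fractions']}")
    print(f"wrote interchange files to {out}")


if __name__ == "__main__":
    main()
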