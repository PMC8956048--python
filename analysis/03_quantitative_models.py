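"""PLSR quantification of the four quality parameters.

Splits the outlier-screened samples 4:1 by Kennard-Stone, runs the
seven-method pretreatment grid (factor counts by 10-fold CV) for PSC,
WSE, ASE and SFT, and reports the winning pretreatment with its RMSEC /
R2cal / RMSEP / R2pre and mean relative error on the validation group.
"""

from pathlib import Path

import pandas as pd

from pcnir import (PRETREATMENTS, PretreatmentSpec, QUALITY_PARAMETERS,
                   kennard_stone_split, pretreatment_grid_search,
                   read_sample_table, read_spectra)

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
DATA = ROOT / "scratch" / "data"  # large intermediates stay out of results
SEED = 1


def main() -> None:
    spectra = read_spectra(DATA / "spectra.csv")
    table = read_sample_table(DATA / "sample_table.csv")
    keep = (DATA / "kept_ids.txt").read_text().split()
    spectra, table = spectra.subset(keep), table.subset(keep)
    split = kennard_stone_split(spectra, ratio=4.0)
    split.write_csv(OUT / "split.csv")
    print(f"Kennard-Stone 4:1 split: {len(split.calibration_ids)} calibration"
          f" / {len(split.validation_ids)} validation")
    methods = [PretreatmentSpec(n) for n in PRETREATMENTS]
    best_rows = []
    for name in QUALITY_PARAMETERS:
        grid = pretreatment_grid_search(spectra, table.response(name), split,
                                        methods, cv_seed=SEED + 202)
        grid.table.to_csv(OUT / f"grid_{name}.csv", index=False)
        best = grid.table.set_index("method").loc[grid.selected]
        best_rows.append({"index": name, "method": grid.selected, **best})
        print(f"\n{name}: selected {grid.selected} "
              f"({int(best.n_factors)} factors) — "
              f"R2cal {best.r2_cal:.3f}, RMSEP {best.rmsep:.3f}, "
              f"R2pre {best.r2_pre:.3f}, RE {best.re_percent:.2f}%")
    pd.DataFrame(best_rows).to_csv(OUT / "best_models.csv", index=False)


if __name__ == "__main__":
    main()
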