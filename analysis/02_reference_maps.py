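"""Reference-cell frequency maps per cohort.

Loads the cohort images from 01, runs nucleus QC, centres every passing
cell on the crossbow template, and averages the actin channel into a
0-255 frequency map per cohort.  QC decisions go to results/; the map
images (PNG) go to scratch/.
"""

import json
import pathlib

import numpy as np
import pandas as pd
import tifffile

from actinquant import micropattern as mp
from actinquant import synth

ROOT = pathlib.Path(__file__).resolve().parents[1]
IMG = ROOT / "scratch" / "images"
OUT = ROOT / "results"


def load_cell(path):
    pages = tifffile.imread(path).astype(float)
    side = json.loads((path.parent / (path.name + ".json")).read_text())
    return mp.CellImageSet(channels=dict(zip(side["pages"], pages)))


def main():
    manifest = pd.read_csv(OUT / "cohort_manifest.csv")
    template = synth.crossbow_mask(256).astype(float)
    rows, maps = [], {}
    for cohort, sub in manifest.groupby("cohort"):
        passed = []
        for cell_id in sub.cell:
            cell = load_cell(IMG / f"{cell_id}.tif")
            status = mp.qc_cell(cell.channels["dapi"])
            if status == mp.QC_PASSED:
                cell = mp.center_on_pattern(cell, template)
                status = cell.qc_status
            if status == mp.QC_PASSED:
                passed.append(cell)
            rows.append({"cell": cell_id, "qc_status": status, "offset_x": cell.centring_offset[0], "offset_y": cell.centring_offset[1]})
        fm = mp.build_frequency_map(passed, "actin")
        maps[cohort] = fm
        from imageio.v3 import imwrite

        imwrite(ROOT / "scratch" / f"refmap_{cohort}.png", fm.map)
    pd.DataFrame(rows).to_csv(OUT / "qc_decisions.csv", index=False)
    for cohort, fm in maps.items():
        print(f"{cohort}: frequency map over {fm.n_cells} cells, range {fm.map.min()}-{fm.map.max()}")


if __name__ == "__main__":
    main()
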