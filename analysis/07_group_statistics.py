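"""Non-parametric comparison of the measured morphometrics across cohorts.

Takes the adhesion-width and foci-count tables from 04, averages within
biological replicate, and runs the Kruskal-Wallis test with Dunn-Holm
pairwise contrasts — the reporting convention of the pipeline (chi2, p,
per-pair adjusted p, medians, n).
"""

import pathlib

import pandas as pd

from actinquant import stats

ROOT = pathlib.Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def run(df, value, label):
    groups = stats.groups_from_frame(df, value=value, group="cohort", replicate="replicate")
    res = stats.compare_groups(groups)
    rows = [
        {"comparison": f"{a} vs {b}", "z": pr.z, "p_raw": pr.p_raw, "p_holm": pr.p_holm}
        for (a, b), pr in ((pr.pair, pr) for pr in res.pairwise)
    ]
    out = pd.DataFrame(rows)
    out.insert(0, "measure", label)
    print(f"{label}: H = {res.chi2:.3f}, p = {res.p:.4g}; medians {res.medians}; n {res.n}")
    return out, res


def main():
    adh = pd.read_csv(OUT / "adhesion_records.csv")
    foci = pd.read_csv(OUT / "foci_counts.csv")
    t1, _ = run(adh, "width_um", "adhesion_width_um")
    t2, _ = run(foci, "n_foci", "foci_per_cell")
    pd.concat([t1, t2]).to_csv(OUT / "group_statistics.csv", index=False)


if __name__ == "__main__":
    main()
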