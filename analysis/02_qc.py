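"""Genotype quality control.

Applies the chip-era rules in fixed order — sample call rate > 0.95, IBS
duplicate removal at 0.95, then marker call rate, MAF (<= 0.05 removed) and
exact HWE (p < 1e-5) — and reports what each rule removed.
"""

import argparse
import pathlib

from wishnet import io
from wishnet.qc import run_qc

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main(indir=None, outdir=None):
    ind = pathlib.Path(indir) if indir else ROOT / "results" / "sim"
    out = pathlib.Path(outdir) if outdir else ROOT / "results" / "qc"
    out.mkdir(parents=True, exist_ok=True)

    g = io.read_genotypes(ind / "genotypes.tsv", "dosage_tsv",
                          ind / "markers.map")
    filtered, report = run_qc(g)
    io.write_dosage_tsv(filtered, out / "genotypes_qc.tsv")
    io.write_map(filtered.gmap, out / "markers_qc.map")
    report.to_tsv(out / "qc_exclusions.tsv")

    print(f"QC: {report.n_animals_before} -> {report.n_animals_after} animals, "
          f"{report.n_markers_before} -> {report.n_markers_after} markers")
    by_rule = report.counts_by_rule()
    for rule, n in by_rule.items():
        print(f"  removed by {rule}: {n}")
    print(f"  thresholds: {report.thresholds}")
    return out


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="indir", default=None)
    ap.add_argument("--out", default=None)
    args = ap.parse_args()
    main(args.indir, args.out)
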