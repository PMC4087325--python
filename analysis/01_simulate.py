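"""Simulate the F2 intercross cohort.

Generates the default desk-scale cohort — 24 founders from two divergent
lines, 78 F1 and 454 F2 animals over 10 chromosomes x 500 SNPs — with two
planted signals: a fixed-divergent major-QTL block on chromosome 1 (the
obesity-index signal) and a rare large-effect haplotype on chromosome 3
(the differential-wiring signal).  Writes genotypes, map, traits, pedigree,
covariance targets and a synthetic gene annotation under results/sim/.
"""

import argparse
import json
import pathlib

import numpy as np

from wishnet import io
from wishnet.annot import GeneAnnotation
from wishnet.simdata import SimConfig, simulate_cross, synthetic_annotation

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main(seed: int, outdir=None):
    out = pathlib.Path(outdir) if outdir else ROOT / "results" / "sim"
    out.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=seed)
    sim = simulate_cross(cfg)

    io.write_dosage_tsv(sim.genotypes, out / "genotypes.tsv")
    io.write_map(sim.genotypes.gmap, out / "markers.map")
    io.write_traits(sim.traits, out / "traits.tsv")
    sim.pedigree.to_csv(out / "pedigree.tsv", sep="\t", index=False)
    sim.causal.to_csv(out / "causal_markers.tsv", sep="\t", index=False)
    io.write_covariance(cfg.traits.P, cfg.traits.names, out / "P.tsv")
    io.write_covariance(cfg.traits.G, cfg.traits.names, out / "G.tsv")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 97])
                                .generate_state(1)[0])
    genes, sets = synthetic_annotation(sim.genotypes.gmap, sim.causal, rng)
    GeneAnnotation(genes)  # validates
    with open(out / "genes.bed", "w") as fh:
        for _, r in genes.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['gene']}\n")
    with open(out / "gene_sets.gmt", "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + members) + "\n")
    with open(out / "sim_config.json", "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, default=str)

    g = sim.genotypes
    print(f"simulated {g.n_animals} animals x {g.n_markers} markers "
          f"(seed {seed})")
    print(f"  missing rate: {g.missing_mask.mean():.4f}")
    print(f"  planted clusters: "
          f"{sim.causal.groupby('cluster').size().to_dict()}")
    print(f"  outputs in {out}")
    return out


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default=None)
    args = ap.parse_args()
    main(args.seed, args.out)
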