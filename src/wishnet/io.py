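"""Readers and writers for the flat-file dialects used by the pipeline.

Genotypes travel either as PLINK PED/MAP (alleles A/B, missing "0 0",
4-column MAP: chrom, marker, cM, bp) or as a dosage TSV (rows = animals,
columns = markers, values 0/1/2, missing "NA").  Dosage counts the A
allele.  Trait tables, covariance matrices and index values are plain TSV;
p-values are written in scientific notation with 6 significant figures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GeneticMap, GenotypeMatrix

__all__ = ["read_genotypes", "write_genotypes", "read_map", "write_map",
           "read_dosage_tsv", "write_dosage_tsv", "read_ped_map", "write_ped_map",
           "read_traits", "write_traits", "read_covariance", "write_covariance",
           "read_oi", "write_oi", "FLOAT_FMT"]

FLOAT_FMT = "%.6g"


# -- map --------------------------------------------------------------------

def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "marker", "cm", "bp"], dtype=str)
    return GeneticMap(df["chrom"].to_numpy(dtype=object),
                      df["marker"].to_numpy(dtype=object),
                      df["bp"].astype(np.int64).to_numpy(),
                      df["cm"].astype(float).to_numpy())


def write_map(gmap: GeneticMap, path) -> None:
    gmap_df = pd.DataFrame({"chrom": gmap.chrom, "marker": gmap.marker,
                            "cm": gmap.cm, "bp": gmap.bp})
    gmap_df.to_csv(path, sep="\t", header=False, index=False,
                   float_format="%.6f")


# -- dosage TSV -------------------------------------------------------------

def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    df = g.to_frame()
    df.index.name = "animal_id"
    out = df.copy()
    obs = out.notna()
    out = out.astype(object)
    out[obs] = df[obs].astype("Int64").astype(object)
    out.to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(path, gmap: GeneticMap | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate animal id {dup!r}")
    if gmap is not None:
        missing = [m for m in gmap.marker if m not in df.columns]
        if missing:
            raise ValueError(f"{path}: markers absent from dosage file: {missing[:5]}")
        df = df[[str(m) for m in gmap.marker]]
    return GenotypeMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float), gmap)


# -- PED/MAP ----------------------------------------------------------------

def write_ped_map(g: GenotypeMatrix, ped_path, map_path,
                  pedigree: pd.DataFrame | None = None) -> None:
    """PED with A/B alleles: dosage counts A; missing is "0 0"."""
    if g.gmap is None:
        raise ValueError("PED/MAP export needs a genetic map")
    write_map(g.gmap, map_path)
    ped_info = {}
    if pedigree is not None:
        ped_info = pedigree.set_index("animal_id")[["sire", "dam"]].to_dict("index")
    code = {0.0: ("B", "B"), 1.0: ("A", "B"), 2.0: ("A", "A")}
    with open(ped_path, "w") as fh:
        for i, aid in enumerate(g.animal_ids):
            par = ped_info.get(aid, {"sire": "0", "dam": "0"})
            fields = ["FAM", aid, str(par.get("sire") or 0),
                      str(par.get("dam") or 0), "0", "-9"]
            row = g.dosages[i]
            for d in row:
                a1, a2 = ("0", "0") if np.isnan(d) else code[d]
                fields.extend([a1, a2])
            fh.write(" ".join(fields) + "\n")


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    gmap = read_map(map_path)
    m = len(gmap)
    animals, rows = [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, "
                    f"got {len(parts)}"
                )
            aid = parts[1]
            if aid in animals:
                raise ValueError(f"{ped_path}:{lineno}: duplicate animal id {aid!r}")
            alleles = parts[6:]
            dos = np.empty(m)
            for j in range(m):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    dos[j] = np.nan
                    continue
                if a1 not in "AB" or a2 not in "AB":
                    raise ValueError(
                        f"{ped_path}:{lineno}: unknown allele {a1!r}/{a2!r} "
                        f"at marker {gmap.marker[j]}"
                    )
                dos[j] = (a1 == "A") + (a2 == "A")
            animals.append(aid)
            rows.append(dos)
    return GenotypeMatrix(animals, np.array(rows), gmap)


def read_genotypes(path, dialect: str = "dosage_tsv",
                   map_path=None) -> GenotypeMatrix:
    """Dispatch on dialect: ``ped_map`` (needs map_path) or ``dosage_tsv``."""
    if dialect == "ped_map":
        if map_path is None:
            raise ValueError("ped_map dialect needs map_path")
        return read_ped_map(path, map_path)
    if dialect == "dosage_tsv":
        gmap = read_map(map_path) if map_path is not None else None
        return read_dosage_tsv(path, gmap)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def write_genotypes(g: GenotypeMatrix, path, dialect: str = "dosage_tsv",
                    map_path=None, pedigree=None) -> None:
    if dialect == "ped_map":
        if map_path is None:
            raise ValueError("ped_map dialect needs map_path")
        write_ped_map(g, path, map_path, pedigree)
    elif dialect == "dosage_tsv":
        write_dosage_tsv(g, path)
        if map_path is not None and g.gmap is not None:
            write_map(g.gmap, map_path)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


# -- trait tables, covariances, index ---------------------------------------

def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_traits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_covariance(mat: np.ndarray, names, path) -> None:
    pd.DataFrame(mat, index=list(names), columns=list(names)).to_csv(
        path, sep="\t", float_format="%.10g")


def read_covariance(path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: covariance row/column names differ")
    return df.to_numpy(dtype=float), list(df.columns)


def write_oi(oi: pd.Series, path) -> None:
    df = pd.DataFrame({"animal_id": oi.index, "OI": oi.to_numpy()})
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_oi(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["OI"].to_numpy(), index=df["animal_id"].astype(str),
                     name="OI")
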