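"""File input/output helpers.

TSV dialects for the phased map, dosage matrix and trait tables live on
their containers (``PhasedMap.read_tsv`` etc.); this module adds trait
tables and an optional VCF export carrying tetraploid dosages in a
DS-style FORMAT field.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .core import DosageMatrix, PhasedMap


def read_trait_tsv(path) -> pd.DataFrame:
    """Read a trait table (columns genotype, trait, year, value)."""
    df = pd.read_csv(path, sep="\t")
    required = {"genotype", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"trait table needs columns {sorted(required)}")
    return df


def write_trait_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_vcf(dosages: DosageMatrix, pmap: PhasedMap, path) -> None:
    """Write dosages as a (sites-only-positions) VCF with a DS field.

    Marker cM positions are scaled to integer coordinates per linkage
    group; genotype dosage goes into the DS FORMAT field (missing
    dosages become '.').
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage (0-4)">')
    header.add_line('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic position in cM">')
    for lg in pmap.lgs:
        length = int(np.ceil(pmap.positions(lg)[-1] * 100)) + 2
        header.contigs.add(f"LG{lg}", length=length)
    for ind in dosages.individuals:
        header.add_sample(ind)
    col = {m: j for j, m in enumerate(dosages.markers)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for _, row in pmap.df.iterrows():
            marker = row["marker"]
            if marker not in col:
                continue
            rec = vcf.new_record(
                contig=f"LG{row['lg']}",
                start=int(round(row["position_cm"] * 100)),
                alleles=("A", "T"),
                id=str(marker),
            )
            rec.info["CM"] = float(row["position_cm"])
            for i, ind in enumerate(dosages.individuals):
                d = dosages.dosage[i, col[marker]]
                rec.samples[ind]["DS"] = None if np.isnan(d) else float(d)
            vcf.write(rec)
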