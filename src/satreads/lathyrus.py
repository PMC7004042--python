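"""Reference characteristics of the major *Lathyrus sativus* satellite repeats.

The grass pea is the worked example shipped with this package: a legume
with a 6.52 Gbp/1C genome whose eleven most abundant satellite families
(FabTR-2 and FabTR-51 through FabTR-60, several with subfamilies) span
monomer lengths from 32 to 660 bp and genome proportions from about 0.1%
to 2.6%.  Monomer lengths drive the synthetic-data defaults and the
periodicity worked examples; genome proportions and the sequencing-run
figures support simple coverage arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Haploid genome size of L. sativus, Mbp/1C.
GENOME_SIZE_MBP = 6_520

#: Ultra-long read data analysed in the worked example: total Gbp retained
#: after discarding reads shorter than 30 kb, and the corresponding read
#: count and length range.
READ_SET_GBP = 4.78
READ_SET_COUNT = 78_563
READ_LENGTH_RANGE_KB = (30, 348)


@dataclass(frozen=True)
class SatelliteFamily:
    """One satellite family or subfamily of the reference set."""

    name: str
    monomer_bp: int
    at_percent: float
    genome_percent: float | None  # None where only the family total is known
    mbp_per_1c: float | None


#: The eleven major satellite families/subfamilies, with monomer length,
#: AT content, and genomic abundance (percent of the genome and Mbp/1C).
FAMILIES: tuple[SatelliteFamily, ...] = (
    SatelliteFamily("FabTR-2", 49, 71.4, 1.700, 110.8),
    SatelliteFamily("FabTR-51", 80, 46.3, 3.101, 202.2),  # family total; -A monomer
    SatelliteFamily("FabTR-51-LAS-A", 80, 46.3, 2.500, 163.0),
    SatelliteFamily("FabTR-51-LAS-B", 79, 51.9, 0.560, 36.5),
    SatelliteFamily("FabTR-51-LAS-C", 118, 50.0, 0.041, 2.7),
    SatelliteFamily("FabTR-52", 55, 47.3, 2.019, 131.6),  # family total; -A monomer
    SatelliteFamily("FabTR-52-LAS-A", 55, 47.3, 2.000, 130.4),
    SatelliteFamily("FabTR-52-LAS-B", 32, 50.0, 0.019, 1.2),
    SatelliteFamily("FabTR-53", 660, 76.6, 2.600, 169.5),  # family total; -A monomer
    SatelliteFamily("FabTR-53-LAS-A", 660, 76.6, None, None),
    SatelliteFamily("FabTR-53-LAS-B", 368, 76.4, None, None),
    SatelliteFamily("FabTR-53-LAS-C", 565, 75.9, None, None),
    SatelliteFamily("FabTR-54", 104, 51.0, 0.840, 54.8),
    SatelliteFamily("FabTR-55", 78, 55.1, 0.480, 31.3),
    SatelliteFamily("FabTR-56", 46, 60.9, 0.250, 16.3),
    SatelliteFamily("FabTR-57", 61, 65.6, 0.130, 8.5),
    SatelliteFamily("FabTR-58", 86, 59.3, 0.140, 9.1),
    SatelliteFamily("FabTR-59", 131, 49.6, 0.110, 7.2),
    SatelliteFamily("FabTR-60", 86, 52.3, 0.110, 7.2),
)


def family(name: str) -> SatelliteFamily:
    for fam in FAMILIES:
        if fam.name == name:
            return fam
    raise KeyError(f"unknown satellite family {name!r}")


def monomer_length(name: str) -> int:
    return family(name).monomer_bp


def genome_coverage(read_gbp: float = READ_SET_GBP,
                    genome_gbp: float = GENOME_SIZE_MBP / 1000) -> float:
    """Fold-coverage of the genome by the read set (e.g. 4.78/6.52 = 0.73x)."""
    return read_gbp / genome_gbp


def abundance_mbp(genome_percent: float,
                  genome_size_mbp: float = GENOME_SIZE_MBP) -> float:
    """Mbp/1C occupied by a repeat at the given genome percentage."""
    return genome_percent / 100.0 * genome_size_mbp
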