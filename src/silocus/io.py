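"""Readers and writers for the formats the pipeline touches.

Tab-separated tables carry the population-survey data (genotypes, B80 link
map, population metadata, silique counts) and the reports (window profiles,
regions, per-gene summaries).  Pooled SNP calls are read either from VCF 4.x
(samples ``SC`` and ``SI`` with allele depths, the AL4 genotype as an
optional third sample or a side table) or from a native one-row-per-pool
TSV.  Readers validate and report the offending line or site; writers are
deterministic, and read(write(x)) is the identity on canonical forms.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import pysam
import yaml

from .bsa import (
    DEFAULT_FIXATION_THRESHOLD,
    DEFAULT_MIN_FREQ,
    DEFAULT_MIN_SCORE,
    DEFAULT_SC_MAX,
    DEFAULT_SI_MIN,
    DEFAULT_STEP_SIZE,
    DEFAULT_WINDOW_SIZE,
    GeneAnnotation,
    PoolCounts,
    RegionCall,
    SnpCall,
    WindowProfile,
    NUCLEOTIDES,
    SC_POOL,
    SI_POOL,
)
from .diversity import B80LinkMap, PopulationMeta, SampleGenotype, UNKNOWN
from .genetics import SiliqueRecord

GENOTYPE_COLUMNS = ("individual", "population", "srk_alleles", "b80_alleles", "phenotype")
SNP_TSV_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "al4",
    "pool",
    "A",
    "C",
    "G",
    "T",
    "depth",
    "score",
    "is_indel",
)
_NA = ("", "NA", "na", ".")


def _split_list(cell: str) -> tuple[str, ...]:
    if cell in _NA:
        return ()
    return tuple(tok.strip() for tok in cell.split(",") if tok.strip())


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


# ---------------------------------------------------------------------------
# genotype tables, link maps, metadata, siliques


def read_genotype_table(
    path: str | Path, exclude_alleles: frozenset[str] | set[str] = frozenset()
) -> list[SampleGenotype]:
    """Read a per-individual S-locus genotype TSV.

    Allele lists are comma-separated; ``?`` marks an unidentified copy and
    ``NA`` an absent field.  Labels in ``exclude_alleles`` (unlinked
    paralogues such as S45) are dropped from the SRK list on input.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("NA")
    _require_columns(df, GENOTYPE_COLUMNS, path)
    exclude = frozenset(exclude_alleles)
    out: list[SampleGenotype] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        srk = _split_list(row["srk_alleles"])
        srk = tuple(a for a in srk if a not in exclude)
        if not srk:
            raise ValueError(f"{path}:{line}: no SRK allele tokens")
        for tok in srk:
            if tok != UNKNOWN and not tok[0].isalnum():
                raise ValueError(f"{path}:{line}: bad allele token {tok!r}")
        try:
            out.append(
                SampleGenotype(
                    individual_id=row["individual"],
                    population=row["population"],
                    srk_alleles=srk,
                    b80_alleles=_split_list(row["b80_alleles"]),
                    phenotype=row["phenotype"] if row["phenotype"] not in _NA else "unknown",
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{line}: {exc}") from exc
    return out


def write_genotype_table(genotypes: list[SampleGenotype], path: str | Path) -> None:
    rows = [
        {
            "individual": g.individual_id,
            "population": g.population,
            "srk_alleles": ",".join(g.srk_alleles),
            "b80_alleles": ",".join(g.b80_alleles) or "NA",
            "phenotype": g.phenotype,
        }
        for g in genotypes
    ]
    pd.DataFrame(rows, columns=list(GENOTYPE_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_linkmap(path: str | Path) -> B80LinkMap:
    """Read the two-column B80-haplotype -> SRK-allele association TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ("b80_hap", "srk_alleles"), path)
    mapping: dict[str, frozenset[str]] = {}
    for i, row in df.iterrows():
        alleles = _split_list(row["srk_alleles"])
        if not alleles:
            raise ValueError(f"{path}:{i + 2}: haplotype {row['b80_hap']!r} maps to nothing")
        mapping[row["b80_hap"]] = frozenset(alleles)
    return B80LinkMap(mapping)


def write_linkmap(linkmap: B80LinkMap, path: str | Path) -> None:
    rows = [
        {"b80_hap": hap, "srk_alleles": ",".join(sorted(alleles))}
        for hap, alleles in sorted(linkmap.mapping.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_population_meta(path: str | Path) -> list[PopulationMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("population", "tm", "cluster", "mating_class"), path)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                PopulationMeta(
                    population=row["population"],
                    outcrossing_rate_tm=float(row["tm"]),
                    cluster=row["cluster"],
                    mating_class=row["mating_class"],
                    exclude_from_tm_mean=(
                        str(row.get("exclude_tm_mean", "no")).lower() in ("yes", "true", "1")
                    ),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 2}: {exc}") from exc
    return out


def read_silique_records(path: str | Path) -> dict[str, SiliqueRecord]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("plant_id", "full", "partial", "empty"), path)
    out = {}
    for i, row in df.iterrows():
        try:
            out[str(row["plant_id"])] = SiliqueRecord(
                full=int(row["full"]), partial=int(row["partial"]), empty=int(row["empty"])
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 2}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# SNP calls: native TSV and VCF dialects


def read_snp_calls(
    path: str | Path,
    dialect: str = "auto",
    al4_table: str | Path | None = None,
) -> list[SnpCall]:
    """Read pooled SNP calls from the native TSV or a VCF.

    ``dialect`` is ``"tsv"``, ``"vcf"`` or ``"auto"`` (by file extension).
    For VCF input without an ``AL4`` sample column, ``al4_table`` can name a
    two-plus-column TSV (``chrom  pos  al4``) supplying the AL4 allele.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "vcf" if path.suffix in (".vcf", ".bcf") or path.name.endswith(".vcf.gz") else "tsv"
    if dialect == "tsv":
        return _read_snp_tsv(path)
    if dialect == "vcf":
        return _read_snp_vcf(path, al4_table)
    raise ValueError(f"unknown SNP dialect {dialect!r}")


def _read_snp_tsv(path: Path) -> list[SnpCall]:
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "al4": str, "ref": str, "pool": str},
        keep_default_na=False, na_values=[],
    )
    _require_columns(df, SNP_TSV_COLUMNS, path)
    sites: dict[tuple[str, int], dict] = {}
    for _, row in df.iterrows():
        key = (str(row["chrom"]), int(row["pos"]))
        counts = {b: int(row[b]) for b in NUCLEOTIDES if int(row[b]) > 0}
        depth = int(row["depth"])
        if sum(counts.values()) != depth:
            raise ValueError(
                f"{path}: depth/count mismatch at {key[0]}:{key[1]} pool {row['pool']}"
            )
        site = sites.setdefault(
            key,
            {
                "ref": str(row["ref"]),
                "al4": None if str(row["al4"]) in _NA else str(row["al4"]),
                "is_indel": str(row["is_indel"]).lower() in ("true", "1"),
                "pools": {},
            },
        )
        site["pools"][str(row["pool"])] = PoolCounts(
            depth=depth, allele_counts=counts, score=float(row["score"])
        )
    return [
        SnpCall(
            chrom=chrom,
            pos=pos,
            ref_base=site["ref"],
            al4_allele=site["al4"],
            pools=site["pools"],
            is_indel=site["is_indel"],
        )
        for (chrom, pos), site in sorted(sites.items())
    ]


def write_snp_tsv(snps: list[SnpCall], path: str | Path) -> None:
    rows = []
    for snp in sorted(snps, key=lambda s: (s.chrom, s.pos)):
        for pool_name in sorted(snp.pools):
            pool = snp.pools[pool_name]
            row = {
                "chrom": snp.chrom,
                "pos": snp.pos,
                "ref": snp.ref_base,
                "al4": snp.al4_allele if snp.al4_allele else "NA",
                "pool": pool_name,
                "depth": pool.depth,
                "score": repr(pool.score),
                "is_indel": snp.is_indel,
            }
            for b in NUCLEOTIDES:
                row[b] = pool.allele_counts.get(b, 0)
            rows.append(row)
    pd.DataFrame(rows, columns=list(SNP_TSV_COLUMNS)).to_csv(path, sep="\t", index=False)


def _read_snp_vcf(path: Path, al4_table: str | Path | None) -> list[SnpCall]:
    al4_lookup: dict[tuple[str, int], str] = {}
    if al4_table is not None:
        adf = pd.read_csv(al4_table, sep="\t", dtype={"chrom": str})
        _require_columns(adf, ("chrom", "pos", "al4"), al4_table)
        for _, row in adf.iterrows():
            al4_lookup[(str(row["chrom"]), int(row["pos"]))] = str(row["al4"])

    snps: list[SnpCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for name in (SC_POOL, SI_POOL):
            if name not in samples:
                raise ValueError(f"{path}: VCF lacks required sample {name!r}")
        has_al4_sample = "AL4" in samples
        for rec in vcf:
            alleles = (rec.ref,) + tuple(rec.alts or ())
            is_indel = any(len(a) != 1 for a in alleles) or "INDEL" in (rec.info or {})
            pools = {}
            for name in (SC_POOL, SI_POOL):
                sample = rec.samples[name]
                ad = sample.get("AD")
                if ad is None:
                    raise ValueError(
                        f"{path}: sample {name} lacks AD at {rec.chrom}:{rec.pos}"
                    )
                counts = {
                    a: int(d)
                    for a, d in zip(alleles, ad)
                    if d is not None and int(d) > 0
                }
                depth = sum(counts.values())
                score = rec.qual if rec.qual is not None else 0.0
                pools[name] = PoolCounts(depth=depth, allele_counts=counts, score=float(score))
            al4: str | None = None
            if has_al4_sample:
                gt = rec.samples["AL4"].get("GT")
                if gt and gt[0] is not None and all(g == gt[0] for g in gt):
                    al4 = alleles[gt[0]]
            else:
                al4 = al4_lookup.get((rec.chrom, rec.pos))
            snps.append(
                SnpCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_base=rec.ref,
                    al4_allele=al4,
                    pools=pools,
                    is_indel=is_indel,
                )
            )
    return snps


def write_snp_vcf(snps: list[SnpCall], path: str | Path) -> None:
    """Write pooled calls as a minimal plain-text VCF 4.2.

    Samples SC and SI carry GT (./.) and AD; the AL4 genotype is a third
    sample with a homozygous GT when the allele is known.
    """
    chroms: dict[str, int] = {}
    for snp in snps:
        chroms[snp.chrom] = max(chroms.get(snp.chrom, 0), snp.pos)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length={l}>" for c, l in sorted(chroms.items())]
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSC\tSI\tAL4",
    ]
    for snp in sorted(snps, key=lambda s: (s.chrom, s.pos)):
        alts: list[str] = []
        for pool in snp.pools.values():
            for a in sorted(pool.allele_counts):
                if a != snp.ref_base and a not in alts:
                    alts.append(a)
        if snp.al4_allele and snp.al4_allele != snp.ref_base and snp.al4_allele not in alts:
            alts.append(snp.al4_allele)
        alleles = (snp.ref_base, *alts)
        qual = max((p.score for p in snp.pools.values()), default=0.0)
        cols = [
            snp.chrom,
            str(snp.pos),
            ".",
            snp.ref_base,
            ",".join(alts) if alts else ".",
            f"{qual:g}",
            "PASS",
            "INDEL" if snp.is_indel else ".",
            "GT:AD",
        ]
        for name in (SC_POOL, SI_POOL):
            pool = snp.pools.get(name)
            if pool is None:
                cols.append("./.:.")
                continue
            ad = ",".join(str(pool.allele_counts.get(a, 0)) for a in alleles)
            cols.append(f"./.:{ad}")
        if snp.al4_allele in alleles:
            idx = alleles.index(snp.al4_allele)
            cols.append(f"{idx}/{idx}:.")
        else:
            cols.append("./.:.")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# annotations


def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based).

    BED columns beyond the fourth are ignored.  In GFF3, ``gene`` features
    become annotations (named by ``ID`` or ``Name``) and ``CDS`` features are
    attached to their gene by the ``Parent`` attribute prefix.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(path)
    return _read_bed(path)


def _read_bed(path: Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 4:
        raise ValueError(f"{path}: BED needs chrom, start, end, name columns")
    return [
        GeneAnnotation(
            name=str(row[3]),
            chrom=str(row[0]),
            start=int(row[1]) + 1,  # 0-based half-open -> 1-based inclusive
            end=int(row[2]),
        )
        for _, row in df.iterrows()
    ]


def _attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        if part.startswith(f"{key}="):
            return part.split("=", 1)[1]
    return None


def _read_gff3(path: Path) -> list[GeneAnnotation]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype={0: str},
        names=["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
    )
    genes: dict[str, dict] = {}
    for _, row in df.iterrows():
        if row["type"] == "gene":
            name = _attr(row["attrs"], "ID") or _attr(row["attrs"], "Name")
            if not name:
                raise ValueError(f"{path}: gene feature without ID/Name")
            genes[name] = {
                "chrom": str(row["chrom"]),
                "start": int(row["start"]),
                "end": int(row["end"]),
                "cds": [],
            }
    for _, row in df.iterrows():
        if row["type"] == "CDS":
            parent = _attr(row["attrs"], "Parent") or ""
            for name in genes:
                if parent == name or parent.startswith(f"{name}."):
                    genes[name]["cds"].append((int(row["start"]), int(row["end"])))
                    break
    return [
        GeneAnnotation(
            name=name,
            chrom=g["chrom"],
            start=g["start"],
            end=g["end"],
            cds=tuple(sorted(g["cds"])),
        )
        for name, g in genes.items()
    ]


# ---------------------------------------------------------------------------
# report writers


def write_window_profiles(profiles: list[WindowProfile], path: str | Path) -> None:
    rows = [
        {
            "chrom": w.chrom,
            "start": w.start,
            "end": w.end,
            "sc_mean": w.mean_divergence.get(SC_POOL, float("nan")),
            "si_mean": w.mean_divergence.get(SI_POOL, float("nan")),
            "n_snps": w.n_snps,
        }
        for w in profiles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_regions(regions: list[RegionCall], path: str | Path) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "n_windows": r.n_windows,
            "sc_mean": r.sc_mean,
            "si_mean": r.si_mean,
        }
        for r in regions
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_windows", "sc_mean", "si_mean"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration and provenance


@dataclass
class RunConfig:
    """Pipeline thresholds, with defaults at the analysis' stated values."""

    min_freq: float = DEFAULT_MIN_FREQ
    min_score: float = DEFAULT_MIN_SCORE
    fixation_threshold: float = DEFAULT_FIXATION_THRESHOLD
    window_size: int = DEFAULT_WINDOW_SIZE
    step_size: int = DEFAULT_STEP_SIZE
    sc_max: float = DEFAULT_SC_MAX
    si_min: float = DEFAULT_SI_MIN
    exclude_alleles: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_freq <= 1.0:
            raise ValueError("min_freq must be in [0, 1]")
        if not 0.0 <= self.fixation_threshold <= 1.0:
            raise ValueError("fixation_threshold must be in [0, 1]")
        if self.window_size <= 0 or self.step_size <= 0:
            raise ValueError("window and step sizes must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def write_provenance(
    path: str | Path, command: str, config: RunConfig, inputs: dict[str, str]
) -> None:
    """Machine-readable record of one run: command, inputs, config hash."""
    from . import __version__

    record = {
        "command": command,
        "inputs": inputs,
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
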