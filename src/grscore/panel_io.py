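"""SNP panel, genotype and phenotype data model and table I/O.

The panel describes a set of biallelic BMI-associated SNPs: for each locus the
BMI-increasing ("effect") allele, the other allele, the effect-allele
frequency (EAF), and membership in the two ancestry-specific score subsets
(EA = loci at genome-wide significance in European-ancestry discovery GWAS,
EAA = loci at genome-wide significance in East-Asian discovery GWAS).

Genotypes are effect-allele dosages in {0, 1, 2}; missing is NaN in memory
and the literal token ``NA`` in tab-delimited files.  A VCF ingestion path
converts arbitrary REF/ALT coding to effect-allele dosage via
:func:`align_alleles`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VALID_ALLELES",
    "MISSING_TOKEN",
    "SnpPanelRecord",
    "GenotypeMatrix",
    "CohortTable",
    "AlignedDosage",
    "PanelError",
    "default_panel_path",
    "read_panel",
    "write_panel",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_vcf_dosages",
    "align_alleles",
    "is_palindromic",
    "classify_weight",
]

VALID_ALLELES = frozenset("ACGT")
MISSING_TOKEN = "NA"

#: columns of the tab-delimited panel format, in canonical order
PANEL_COLUMNS = [
    "gene", "rsid", "effect_allele", "other_allele", "eaf",
    "in_ea_set", "in_eaa_set", "ref_beta", "ref_se", "imputed",
]

PHENOTYPE_COLUMNS = [
    "individual_id", "bmi", "body_fat_pct", "trunk_fat_pct", "leg_fat_pct",
    "age", "sex", "region", "pc1", "pc2", "pa_level",
]

PA_LEVELS = ("low", "moderate", "high")
PA_CODE = {"low": 0, "moderate": 1, "high": 2}
WEIGHT_CLASSES = ("normal", "overweight", "obese")


class PanelError(ValueError):
    """Raised for malformed panel, genotype or phenotype inputs."""


@dataclass(frozen=True)
class SnpPanelRecord:
    """One biallelic locus of the risk-score panel.

    ``eaf`` is the frequency of the BMI-increasing allele in the study
    population; ``ref_beta``/``ref_se`` optionally carry an external
    (discovery-cohort) per-allele effect in kg/m² for heterogeneity tests.
    """

    gene: str
    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float
    in_ea_set: bool = False
    in_eaa_set: bool = False
    ref_beta: float | None = None
    ref_se: float | None = None
    imputed: bool = False

    def __post_init__(self) -> None:
        for name in ("effect_allele", "other_allele"):
            a = getattr(self, name)
            if a not in VALID_ALLELES:
                raise PanelError(f"{self.rsid}: invalid {name} {a!r}")
        if self.effect_allele == self.other_allele:
            raise PanelError(f"{self.rsid}: effect and other allele are identical")
        if not 0.0 <= self.eaf <= 1.0:
            raise PanelError(f"{self.rsid}: eaf {self.eaf} outside [0, 1]")
        if self.ref_se is not None and self.ref_se <= 0:
            raise PanelError(f"{self.rsid}: ref_se must be positive")


@dataclass
class GenotypeMatrix:
    """Individuals × SNPs effect-allele dosages; missing is NaN.

    Non-missing entries must be exactly 0, 1 or 2.
    """

    individual_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray  # float array, NaN = missing
    strand_ambiguous: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.individual_ids) or m != len(self.snp_ids):
            raise PanelError("dosage shape does not match id lists")
        if len(set(self.individual_ids)) != n:
            raise PanelError("duplicate individual_ids")
        if len(set(self.snp_ids)) != m:
            raise PanelError("duplicate snp_ids")
        obs = self.dosage[~np.isnan(self.dosage)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            bad = obs[~np.isin(obs, (0.0, 1.0, 2.0))][0]
            raise PanelError(f"dosage value {bad!r} outside {{0,1,2,NA}}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def column(self, rsid: str) -> np.ndarray:
        return self.dosage[:, self.snp_ids.index(rsid)]

    def genotype_counts(self, rsid: str) -> tuple[int, int, int]:
        """Non-missing (n0, n1, n2) dosage counts for one SNP."""
        col = self.column(rsid)
        obs = col[~np.isnan(col)]
        return tuple(int((obs == k).sum()) for k in (0, 1, 2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.individual_ids,
                            columns=self.snp_ids)


@dataclass
class CohortTable:
    """Per-individual phenotypes and covariates.

    Wraps a DataFrame with the canonical phenotype columns; ``weight_class``
    is always (re)derived from ``bmi`` so the two can never disagree.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.data.columns]
        if missing:
            raise PanelError(f"phenotype table lacks columns: {missing}")
        if self.data["individual_id"].duplicated().any():
            dup = self.data["individual_id"][self.data["individual_id"].duplicated()].iloc[0]
            raise PanelError(f"duplicate individual_id {dup!r}")
        bad_pa = set(self.data["pa_level"].dropna()) - set(PA_LEVELS)
        if bad_pa:
            raise PanelError(f"unknown pa_level values: {sorted(bad_pa)}")
        bad_sex = set(self.data["sex"].dropna()) - {"male", "female"}
        if bad_sex:
            raise PanelError(f"unknown sex values: {sorted(bad_sex)}")
        self.data = self.data.copy()
        self.data["weight_class"] = self.data["bmi"].map(classify_weight)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def pa_code(self) -> pd.Series:
        """Ordinal physical-activity coding: low=0, moderate=1, high=2."""
        return self.data["pa_level"].map(PA_CODE)


class AlignedDosage(NamedTuple):
    """Effect-allele dosage after REF/ALT orientation, with strand flag."""

    dosage: int
    strand_ambiguous: bool


def default_panel_path() -> Path:
    """Path of the packaged 28-SNP panel table."""
    return Path(str(resources.files("grscore").joinpath("data/panel_28snp.tsv")))


def _parse_optional_float(tok: str, what: str, rsid: str) -> float | None:
    if tok in ("", MISSING_TOKEN):
        return None
    try:
        return float(tok)
    except ValueError:
        raise PanelError(f"{rsid}: cannot parse {what} {tok!r}") from None


def _parse_bool(tok: str, what: str, rsid: str) -> bool:
    if tok in ("1", "true", "True"):
        return True
    if tok in ("0", "false", "False", "", MISSING_TOKEN):
        return False
    raise PanelError(f"{rsid}: cannot parse {what} {tok!r}")


def read_panel(path: str | Path) -> list[SnpPanelRecord]:
    """Read a tab-delimited SNP panel into records, in file order.

    Required columns: gene, rsid, effect_allele, other_allele, eaf.
    Optional: in_ea_set, in_eaa_set, ref_beta, ref_se, imputed.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = PANEL_COLUMNS[:5]
        missing = [c for c in required if c not in header]
        if missing:
            raise PanelError(f"panel header lacks columns: {missing}")
        idx = {c: header.index(c) for c in header}
        records: list[SnpPanelRecord] = []
        seen: set[str] = set()
        for line in fh:
            if not line.strip():
                continue
            tok = line.rstrip("\n").split("\t")
            row = {c: tok[i] for c, i in idx.items() if i < len(tok)}
            rsid = row["rsid"]
            if rsid in seen:
                raise PanelError(f"duplicate rsid {rsid!r} in panel")
            seen.add(rsid)
            records.append(SnpPanelRecord(
                gene=row["gene"],
                rsid=rsid,
                effect_allele=row["effect_allele"],
                other_allele=row["other_allele"],
                eaf=float(row["eaf"]),
                in_ea_set=_parse_bool(row.get("in_ea_set", "0"), "in_ea_set", rsid),
                in_eaa_set=_parse_bool(row.get("in_eaa_set", "0"), "in_eaa_set", rsid),
                ref_beta=_parse_optional_float(row.get("ref_beta", MISSING_TOKEN), "ref_beta", rsid),
                ref_se=_parse_optional_float(row.get("ref_se", MISSING_TOKEN), "ref_se", rsid),
                imputed=_parse_bool(row.get("imputed", "0"), "imputed", rsid),
            ))
    return records


def _fmt_optional(x: float | None) -> str:
    return MISSING_TOKEN if x is None else format(x, "g")


def write_panel(records: Sequence[SnpPanelRecord], path: str | Path) -> None:
    """Write records in the canonical tab-delimited panel format."""
    with open(path, "w") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join([
                r.gene, r.rsid, r.effect_allele, r.other_allele,
                format(r.eaf, ".2f"),
                str(int(r.in_ea_set)), str(int(r.in_eaa_set)),
                _fmt_optional(r.ref_beta), _fmt_optional(r.ref_se),
                str(int(r.imputed)),
            ]) + "\n")


def load_default_panel() -> list[SnpPanelRecord]:
    """The packaged 28-SNP panel (24 EA, 11 EAA, 7 shared)."""
    return read_panel(default_panel_path())


def read_genotypes(path: str | Path, panel: Sequence[SnpPanelRecord]) -> GenotypeMatrix:
    """Read a tab-delimited dosage table restricted to the panel SNPs.

    First column is ``individual_id``; every other column header is an rsID.
    Cells are 0/1/2 or ``NA``.  Columns whose rsID is not in the panel are
    dropped with a warning; the kept columns are reordered to panel order.
    """
    panel_ids = [r.rsid for r in panel]
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "individual_id":
            raise PanelError("first genotype column must be individual_id")
        file_snps = header[1:]
        unknown = [s for s in file_snps if s not in panel_ids]
        if unknown:
            warnings.warn(
                f"dropping {len(unknown)} genotype column(s) not in panel: {unknown}",
                stacklevel=2,
            )
        keep = [s for s in panel_ids if s in file_snps]
        col_of = {s: file_snps.index(s) + 1 for s in keep}
        ids: list[str] = []
        rows: list[list[float]] = []
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            tok = line.rstrip("\n").split("\t")
            ids.append(tok[0])
            row = []
            for s in keep:
                cell = tok[col_of[s]]
                if cell == MISSING_TOKEN:
                    row.append(np.nan)
                elif cell in ("0", "1", "2"):
                    row.append(float(cell))
                else:
                    raise PanelError(
                        f"invalid dosage {cell!r} at line {ln}, column {s}"
                    )
            rows.append(row)
    dosage = np.array(rows, dtype=float).reshape(len(ids), len(keep))
    return GenotypeMatrix(individual_ids=ids, snp_ids=keep, dosage=dosage)


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual_id\t" + "\t".join(gm.snp_ids) + "\n")
        for i, iid in enumerate(gm.individual_ids):
            cells = [
                MISSING_TOKEN if np.isnan(d) else str(int(d))
                for d in gm.dosage[i]
            ]
            fh.write(iid + "\t" + "\t".join(cells) + "\n")


def read_phenotypes(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN],
                     keep_default_na=False, dtype={"individual_id": str})
    return CohortTable(df)


def write_phenotypes(cohort: CohortTable, path: str | Path) -> None:
    out = cohort.data[PHENOTYPE_COLUMNS]
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN,
               float_format="%g")


def is_palindromic(record: SnpPanelRecord) -> bool:
    """True for A/T and C/G SNPs, whose strand cannot be resolved from alleles."""
    return {record.effect_allele, record.other_allele} in ({"A", "T"}, {"C", "G"})


def align_alleles(record: SnpPanelRecord, ref: str, alt: str,
                  alt_count: int) -> AlignedDosage:
    """Convert an ALT-allele count to an effect-allele dosage.

    Requires {ref, alt} == {effect_allele, other_allele}; returns
    ``alt_count`` when ALT is the effect allele, else ``2 - alt_count``.
    Palindromic records are flagged strand-ambiguous (never auto-flipped).
    """
    if {ref, alt} != {record.effect_allele, record.other_allele}:
        raise PanelError(
            f"{record.rsid}: site alleles {ref}/{alt} do not match panel "
            f"{record.effect_allele}/{record.other_allele}"
        )
    if alt_count not in (0, 1, 2):
        raise PanelError(f"{record.rsid}: alt_count {alt_count} outside 0..2")
    dosage = alt_count if alt == record.effect_allele else 2 - alt_count
    return AlignedDosage(dosage=dosage, strand_ambiguous=is_palindromic(record))


def read_vcf_dosages(path: str | Path, panel: Sequence[SnpPanelRecord]) -> GenotypeMatrix:
    """Ingest GT genotypes from a VCF, matched to panel records by the ID column.

    Uncalled genotypes (./.) become missing; sites with a missing ID are
    skipped with a warning; multiallelic sites and allele-set mismatches are
    errors.  Palindromic panel SNPs are recorded in ``strand_ambiguous``.
    """
    from cyvcf2 import VCF

    by_rsid = {r.rsid: r for r in panel}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    ambiguous: set[str] = set()
    for variant in vcf:
        vid = variant.ID
        if vid is None or vid == ".":
            warnings.warn(f"skipping VCF site {variant.CHROM}:{variant.POS} "
                          "with missing ID", stacklevel=2)
            continue
        rec = by_rsid.get(vid)
        if rec is None:
            continue
        if len(variant.ALT) != 1:
            raise PanelError(f"{vid}: multiallelic site not supported")
        ref, alt = variant.REF, variant.ALT[0]
        col = np.full(len(samples), np.nan)
        # gt_types is unreliable for half-calls; use genotypes directly
        for i, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) < 2:
                continue  # uncalled -> missing
            aligned = align_alleles(rec, ref, alt, int(sum(alleles)))
            col[i] = aligned.dosage
            if aligned.strand_ambiguous:
                ambiguous.add(vid)
        columns[vid] = col
    keep = [r.rsid for r in panel if r.rsid in columns]
    dosage = (np.column_stack([columns[s] for s in keep])
              if keep else np.empty((len(samples), 0)))
    return GenotypeMatrix(individual_ids=samples, snp_ids=keep,
                          dosage=dosage, strand_ambiguous=ambiguous)


def classify_weight(bmi: float) -> str:
    """Weight class under the Chinese BMI cut-offs.

    normal: BMI < 24; overweight: 24 ≤ BMI < 28; obese: BMI ≥ 28 (kg/m²).
    """
    bmi = float(bmi)
    if not np.isfinite(bmi) or bmi <= 0:
        raise PanelError(f"invalid BMI {bmi!r}")
    if bmi < 24.0:
        return "normal"
    if bmi < 28.0:
        return "overweight"
    return "obese"
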