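"""Readers and writers for the pipeline's file formats.

Genotypes travel as biallelic VCF with a GT field (1-based positions;
multi-allelic records are rejected with their record context).  Everything
else is headered TSV: subject tables, long-format event tables, variant
annotations, code maps.  Every run can write a JSON manifest recording the
seed, a parameter hash, and input/output digests, so identical inputs are
verifiable against identical result digests.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, VariantRecord

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_subject_table",
    "read_event_table",
    "read_annotation_table",
    "read_code_map",
    "write_annotation_table",
    "attach_annotations",
    "RunManifest",
    "file_digest",
]

SUBJECT_REQUIRED = ("subject_id", "status")
EVENT_REQUIRED = ("subject_id", "code")
ANNOTATION_REQUIRED = ("variant_id", "gene", "cds_pos", "consequence",
                       "polyphen_label", "sift_label", "domain")


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> Path:
    """Write a minimal biallelic GT-only VCF (v4.2, 1-based positions)."""
    path = Path(path)
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({v.chrom for v in genotypes.variants})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.subject_ids)
            + "\n"
        )
        order = np.argsort([(v.chrom, v.pos) for v in genotypes.variants], axis=0)[:, 1] \
            if genotypes.n_variants else []
        for j in order:
            v = genotypes.variants[j]
            col = genotypes.dosages[:, j]
            gts = "\t".join("./." if np.isnan(x) else gt_of[x] for x in col)
            fh.write(f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")
    return path


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic VCF into a dosage matrix (alternate-allele count).

    Missing genotypes become NaN; a multi-allelic record raises with its
    record number and position.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    cols, meta = [], []
    for i, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            raise ValueError(
                f"record {i} at {rec.CHROM}:{rec.POS} is not biallelic "
                f"(ALT={','.join(rec.ALT) or '.'}); split or drop it first"
            )
        # gts012: 0/1/2 alt-allele count, 3 = missing
        g = rec.gt_types.astype(float)
        g[g == 3] = np.nan
        cols.append(g)
        meta.append(
            VariantRecord(
                variant_id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0],
            )
        )
    vcf.close()
    if not cols:
        raise ValueError(f"no records in {path}")
    return GenotypeMatrix(np.column_stack(cols), samples, meta)


def _read_tsv(path: str | Path, required: tuple, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "code": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table {path} lacks required columns {missing}")
    return df


def read_subject_table(path: str | Path, genotypes: GenotypeMatrix | None = None) -> pd.DataFrame:
    """Read the subject/covariate TSV; validates the id join when genotypes
    are supplied (genotyped subjects missing from the table are an error)."""
    df = _read_tsv(path, SUBJECT_REQUIRED, "subject")
    if genotypes is not None:
        missing = sorted(set(genotypes.subject_ids) - set(df["subject_id"]))
        if missing:
            raise ValueError(
                f"{len(missing)} genotyped subjects absent from {path}: {missing}"
            )
        df = df.set_index("subject_id").loc[genotypes.subject_ids].reset_index()
    return df


def read_event_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, EVENT_REQUIRED, "event")


def read_code_map(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ("code", "phenotype"), "code map")


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ANNOTATION_REQUIRED, "annotation")


def write_annotation_table(genotypes: GenotypeMatrix, path: str | Path) -> Path:
    rows = [
        {
            "variant_id": v.variant_id, "gene": v.gene if v.gene else "",
            "cds_pos": v.cds_pos if v.cds_pos is not None else "",
            "consequence": v.consequence or "",
            "polyphen_label": v.polyphen or "", "sift_label": v.sift or "",
            "domain": v.domain or "",
        }
        for v in genotypes.variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def attach_annotations(genotypes: GenotypeMatrix, annotations: pd.DataFrame) -> GenotypeMatrix:
    """Fill VariantRecord fields from an annotation table (by variant_id)."""
    ann = annotations.set_index("variant_id")
    out = genotypes.copy()
    for v in out.variants:
        if v.variant_id not in ann.index:
            continue
        row = ann.loc[v.variant_id]
        v.gene = row["gene"] or None
        v.cds_pos = int(row["cds_pos"]) if str(row["cds_pos"]) not in ("", "nan") else None
        v.consequence = row["consequence"] or None
        v.polyphen = row["polyphen_label"] or None
        v.sift = row["sift_label"] or None
        v.domain = row["domain"] or None
    return out


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written once per CLI / pipeline run."""

    command: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)    # path -> sha256
    outputs: dict = field(default_factory=dict)   # path -> sha256
    package_version: str = "0.1.0"
    started: float = field(default_factory=time.time)
    finished: float | None = None

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.config, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()

    def add_input(self, path: str | Path):
        self.inputs[str(path)] = file_digest(path)

    def add_output(self, path: str | Path):
        self.outputs[str(path)] = file_digest(path)

    def write(self, path: str | Path) -> Path:
        self.finished = time.time()
        doc = asdict(self)
        doc["config_hash"] = self.config_hash
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, default=str)
        return Path(path)
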