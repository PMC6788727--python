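"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as uncompressed VCF (GT field, INFO GENE= tag) or as a
PLINK-style .raw TSV with a sidecar SNP annotation table; volumes as NIfTI
(one per subject plus a manifest TSV); covariates, expression, PANSS and
all reports as TSV with headers; ground truth as JSON plus NIfTI masks.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .association import GMVImageSet
from .coexpression import ExpressionSet
from .genotypes import MISSING, GenotypeMatrix

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_GT_PARSE = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "./.": MISSING,
             "0|0": 0, "0|1": 1, "1|0": 1, "1|1": 2, ".|.": MISSING}


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_vcf(g: GenotypeMatrix, path) -> Path:
    path = Path(path)
    meta = g.snp_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Annotated gene symbol">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(meta["chrom"].unique()):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.subject_ids) + "\n")
        for col, (snp, row) in enumerate(meta.iterrows()):
            gts = "\t".join(_GT_CODE[int(c)] for c in g.calls[:, col])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{snp}\tA\tC\t.\t.\tGENE={row['gene']}\tGT\t{gts}\n")
    return path


def read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    calls, rows = [], []
    for variant in vcf:
        alt_counts = variant.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        mapped = np.select(
            [alt_counts == 0, alt_counts == 1, alt_counts == 3],
            [0, 1, 2],
            default=MISSING,
        ).astype(np.int8)
        calls.append(mapped)
        rows.append(
            {
                "snp": variant.ID,
                "gene": variant.INFO.get("GENE"),
                "chrom": int(variant.CHROM),
                "pos": int(variant.POS),
            }
        )
    meta = pd.DataFrame(rows).set_index("snp")
    return GenotypeMatrix(calls=np.array(calls, dtype=np.int8).T, snp_meta=meta, subject_ids=subjects)


def write_raw(g: GenotypeMatrix, path, annot_path=None) -> tuple[Path, Path]:
    """PLINK .raw-style TSV plus a SNP annotation sidecar (gene/chrom/pos)."""
    path = Path(path)
    annot_path = Path(annot_path) if annot_path else path.with_suffix(".annot.tsv")
    df = pd.DataFrame(
        g.calls.astype(object), index=pd.Index(g.subject_ids, name="IID"), columns=g.snp_ids
    )
    df = df.where(df != MISSING, other=pd.NA)
    df.to_csv(path, sep="\t", na_rep="NA")
    g.snp_meta.to_csv(annot_path, sep="\t")
    return path, annot_path


def read_raw(path, annot_path=None) -> GenotypeMatrix:
    path = Path(path)
    annot_path = Path(annot_path) if annot_path else path.with_suffix(".annot.tsv")
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(annot_path, sep="\t", index_col=0)
    calls = df.to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    meta = meta.loc[df.columns]
    meta.index.name = "snp"
    return GenotypeMatrix(calls=calls, snp_meta=meta, subject_ids=list(df.index))


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def write_gmv(gmv: GMVImageSet, out_dir, manifest_name="gmv_manifest.tsv") -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sid in enumerate(gmv.subject_ids):
        fn = out_dir / f"gmv_{sid}.nii"
        nib.Nifti1Image(gmv.volumes[i].astype(np.float32), gmv.affine).to_filename(fn)
        rows.append({"subject": sid, "path": fn.name})
    manifest = out_dir / manifest_name
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_gmv(manifest_path) -> GMVImageSet:
    manifest_path = Path(manifest_path)
    rows = pd.read_csv(manifest_path, sep="\t")
    vols, subjects = [], []
    affine = None
    for _, row in rows.iterrows():
        img = nib.load(manifest_path.parent / row["path"])
        vols.append(np.asarray(img.dataobj, dtype=float))
        subjects.append(row["subject"])
        affine = img.affine
    voxel = float(np.abs(affine[0, 0]))
    return GMVImageSet(volumes=np.stack(vols), subject_ids=subjects, voxel_size_mm=voxel, affine=affine)


def write_mask_nifti(mask: np.ndarray, path, voxel_size_mm: float = 1.5) -> Path:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.Nifti1Image(np.asarray(mask).astype(np.int16), affine).to_filename(str(path))
    return Path(path)


def write_map_nifti(data: np.ndarray, path, voxel_size_mm: float = 1.5) -> Path:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.Nifti1Image(np.asarray(data).astype(np.float32), affine).to_filename(str(path))
    return Path(path)


def read_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, index=True) -> Path:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return Path(path)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_expression(expr: ExpressionSet, matrix_path, meta_path) -> None:
    expr.matrix.to_csv(matrix_path, sep="\t")
    expr.sample_meta.to_csv(meta_path, sep="\t")


def read_expression(matrix_path, meta_path) -> ExpressionSet:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionSet(matrix=matrix, sample_meta=meta)


def write_truth(truth, out_dir, voxel_size_mm: float = 1.5) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mask_files = []
    for i, mask in enumerate(truth.true_cluster_masks):
        fn = out_dir / f"truth_mask_{i:02d}.nii"
        write_mask_nifti(mask, fn, voxel_size_mm)
        mask_files.append(fn.name)
    payload = {
        "causal_snp_ids": sorted(truth.causal_snp_ids),
        "causal_gene_ids": sorted(truth.causal_gene_ids),
        "true_group_labels": {k: int(v) for k, v in truth.true_group_labels.items()},
        "mask_files": mask_files,
        "planted_modules": [
            {"genes": list(m.genes), "region": m.region, "stage": m.stage, "rho": m.rho}
            for m in truth.planted_modules
        ],
    }
    path = out_dir / "ground_truth.json"
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_truth(path):
    from .simulate import GroundTruth, ModuleSpec

    path = Path(path)
    payload = json.loads(path.read_text())
    masks = [read_nifti(path.parent / fn).astype(bool) for fn in payload["mask_files"]]
    labels = pd.Series(payload["true_group_labels"], name="group").astype(int)
    labels.index.name = "subject"
    return GroundTruth(
        causal_snp_ids=set(payload["causal_snp_ids"]),
        causal_gene_ids=set(payload["causal_gene_ids"]),
        true_cluster_masks=masks,
        true_group_labels=labels,
        planted_modules=[
            ModuleSpec(genes=tuple(m["genes"]), region=m["region"], stage=m["stage"], rho=m["rho"])
            for m in payload["planted_modules"]
        ],
    )
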