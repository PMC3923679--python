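"""PLINK 1 bed/bim/fam reading and writing, plus model/score text formats.

The bed payload is variant-major: after the three header bytes
(0x6c, 0x1b, 0x01), each variant occupies ceil(n_samples/4) bytes, four
samples per byte packed little-endian (lowest bit pair = first sample).
Two-bit genotype codes map to A1-allele dosages as

    00 -> 2 (hom A1)    01 -> missing    10 -> 1 (het)    11 -> 0 (hom A2)

fam phenotypes use the 1=control / 2=case convention and are mapped to
{-1, +1}; anything else becomes unknown (0).
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MISSING, VARIANT_COLUMNS, GenotypeData
from .models import ConsensusModel

MAGIC = bytes([0x6C, 0x1B])
VARIANT_MAJOR = 0x01
SAMPLE_MAJOR = 0x00

# two-bit code -> A1 dosage
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

# 256-entry lookup: byte -> 4 dosages (LSB pair first)
_BYTE_LUT = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _k in range(4):
        _BYTE_LUT[_b, _k] = _CODE_TO_DOSAGE[(_b >> (2 * _k)) & 0b11]


def bed_payload_size(n_samples: int, n_snps: int) -> int:
    """Exact bed size in bytes: 3 header + n_snps * ceil(n_samples/4)."""
    return 3 + n_snps * ((n_samples + 3) // 4)


def read_plink(prefix: str | os.PathLike) -> GenotypeData:
    """Read a PLINK 1 ``prefix.bed/.bim/.fam`` triple into :class:`GenotypeData`."""
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise FileNotFoundError(f"missing PLINK file: {prefix.with_suffix(ext)}")

    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    pheno = np.zeros(len(fam), dtype=np.int8)
    raw = pd.to_numeric(fam["pheno"], errors="coerce")
    pheno[raw == 1] = -1
    pheno[raw == 2] = 1
    samples = pd.DataFrame({"fid": fam["fid"], "iid": fam["iid"], "phenotype": pheno})

    if prefix.with_suffix(".bim").stat().st_size == 0:
        variants = pd.DataFrame(columns=VARIANT_COLUMNS)
    else:
        variants = pd.read_csv(
            prefix.with_suffix(".bim"),
            sep=r"\s+",
            header=None,
            names=VARIANT_COLUMNS,
            dtype={"chrom": str, "id": str, "a1": str, "a2": str},
        )
    n, p = len(samples), len(variants)

    blob = prefix.with_suffix(".bed").read_bytes()
    if len(blob) < 3 or blob[:2] != MAGIC:
        raise ValueError(f"{prefix.with_suffix('.bed')}: not a PLINK 1 bed file (bad magic bytes)")
    if blob[2] == SAMPLE_MAJOR:
        raise ValueError("sample-major bed layout is not supported; re-export variant-major")
    if blob[2] != VARIANT_MAJOR:
        raise ValueError(f"unknown bed mode byte 0x{blob[2]:02x}")
    bpv = (n + 3) // 4
    expected = 3 + p * bpv
    if len(blob) != expected:
        raise ValueError(
            f"bed payload is {len(blob)} bytes but {expected} expected for "
            f"{n} samples x {p} variants"
        )

    if p == 0 or n == 0:
        dosages = np.empty((n, p), dtype=np.int8)
    else:
        raw_bytes = np.frombuffer(blob, dtype=np.uint8, offset=3).reshape(p, bpv)
        # (p, bpv, 4) -> (p, 4*bpv) -> trim padding -> (n, p)
        dosages = _BYTE_LUT[raw_bytes].reshape(p, 4 * bpv)[:, :n].T.copy()

    return GenotypeData(dosages=dosages, variants=variants, samples=samples)


def write_plink(data: GenotypeData, prefix: str | os.PathLike) -> None:
    """Write ``data`` as a PLINK 1 bed/bim/fam triple under ``prefix``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, p = data.n_samples, data.n_snps

    pheno_out = np.full(n, -9, dtype=int)
    pheno = data.phenotype
    pheno_out[pheno == -1] = 1
    pheno_out[pheno == 1] = 2
    fam = pd.DataFrame(
        {
            "fid": data.samples["fid"],
            "iid": data.samples["iid"],
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": pheno_out,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    data.variants[VARIANT_COLUMNS].to_csv(
        prefix.with_suffix(".bim"), sep="\t", header=False, index=False
    )

    bpv = (n + 3) // 4
    codes = np.empty((p, 4 * bpv), dtype=np.uint8)
    padded = np.zeros((p, 4 * bpv), dtype=np.int8)
    padded[:, :n] = data.dosages.T
    for dos, code in _DOSAGE_TO_CODE.items():
        codes[padded == dos] = code
    codes[:, n:] = 0  # trailing positions in the final byte pad with zero bits
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes.reshape(p, bpv, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(MAGIC + bytes([VARIANT_MAJOR]))
        fh.write(packed.tobytes())


_INTERCEPT_RE = re.compile(r"intercept\s*[:=]\s*([-+0-9.eE]+)", re.IGNORECASE)
_MODEL_COLUMNS = ["snp_id", "effect_allele", "other_allele", "weight", "stability", "mean_dosage"]


def write_model(model: ConsensusModel, path: str | os.PathLike) -> None:
    """Serialize a consensus model as a tab-separated scoring table.

    Header comment lines carry the intercept and the counted-allele
    convention; the body has one row per SNP with the effect (A1) allele,
    weight, selection stability (%), and training mean dosage.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    other = (
        model.other_allele
        if model.other_allele is not None
        else np.full(model.n_snps, ".", dtype=object)
    )
    mean_d = (
        model.mean_dosage
        if model.mean_dosage is not None
        else np.full(model.n_snps, np.nan)
    )
    with open(path, "w") as fh:
        fh.write("# genomic risk score model\n")
        fh.write("# dosage counts the effect_allele (A1 convention)\n")
        fh.write(f"# intercept: {model.intercept:.10g}\n")
        if model.target_size is not None:
            fh.write(f"# target_size: {model.target_size}\n")
        fh.write("\t".join(_MODEL_COLUMNS) + "\n")
        for j in range(model.n_snps):
            fh.write(
                f"{model.snp_id[j]}\t{model.effect_allele[j]}\t{other[j]}\t"
                f"{model.weights[j]:.10g}\t{model.stability[j]:.10g}\t{mean_d[j]:.10g}\n"
            )


def read_model(path: str | os.PathLike) -> ConsensusModel:
    """Parse a model table written by :func:`write_model`.

    The intercept must appear on a header line such as
    ``# intercept: -0.757226`` (a unicode minus sign is accepted).
    """
    path = Path(path)
    intercept = None
    target_size = None
    with open(path) as fh:
        lines = fh.read().replace("−", "-").splitlines()
    body: list[str] = []
    for line in lines:
        if line.startswith("#") or (intercept is None and "ntercept" in line):
            m = _INTERCEPT_RE.search(line)
            if m:
                intercept = float(m.group(1))
            m2 = re.search(r"target_size\s*[:=]\s*(\d+)", line)
            if m2:
                target_size = int(m2.group(1))
        elif line.strip():
            body.append(line)
    if intercept is None:
        raise ValueError(f"{path}: no intercept header line found")
    if not body:
        raise ValueError(f"{path}: empty model table")
    header = body[0].split("\t")
    if header[0] != "snp_id":
        raise ValueError(f"{path}: unexpected model table header {header!r}")
    df = pd.DataFrame([ln.split("\t") for ln in body[1:]], columns=header)
    if df["snp_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate SNP ids in model table")
    stability = df["stability"].astype(float).to_numpy()
    if np.any(stability < 0) or np.any(stability > 100):
        raise ValueError(f"{path}: stability values outside [0, 100]")
    mean_dosage = (
        df["mean_dosage"].astype(float).to_numpy() if "mean_dosage" in df else None
    )
    other = df["other_allele"].to_numpy(dtype=object) if "other_allele" in df else None
    return ConsensusModel(
        snp_id=df["snp_id"].to_numpy(dtype=object),
        effect_allele=df["effect_allele"].to_numpy(dtype=object),
        other_allele=other,
        weights=df["weight"].astype(float).to_numpy(),
        stability=stability,
        intercept=intercept,
        mean_dosage=mean_dosage,
        target_size=target_size,
    )


def write_scores(sample_ids, raw, path, probability=None) -> None:
    """Score output: tab-separated (sample id, raw GRS[, probability])."""
    df = pd.DataFrame({"iid": sample_ids, "score": raw})
    if probability is not None:
        df["probability"] = probability
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"iid": str})


def read_plink_pheno(fam_path) -> pd.DataFrame:
    """Sample ids and {-1,+1,0} phenotypes from a fam file."""
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    pheno = np.zeros(len(fam), dtype=np.int8)
    raw = pd.to_numeric(fam["pheno"], errors="coerce")
    pheno[raw == 1] = -1
    pheno[raw == 2] = 1
    return pd.DataFrame({"iid": fam["iid"], "phenotype": pheno})
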