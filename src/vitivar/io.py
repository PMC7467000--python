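"""Reading and writing the pipeline's on-disk formats.

VCF 4.2 with ``GT:AD:DP`` genotypes and the hard-filter INFO
annotations is the interchange format for call sets; sample metadata
travels as a four-column TSV; ground-truth genotypes as a TSV matrix
with key=value header comments; repeat tracts as BED (0-based
half-open). Reading goes through cyvcf2 (htslib), so anything another
tool writes in the same convention is accepted too.
"""

from __future__ import annotations

import json
import os
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .callset import HET, HOM_ALT, HOM_REF, INFO_FIELDS, MISSING, CohortCallset
from .errors import DataError

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import TruthSet

_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
# cyvcf2 gts012 codes: 0=hom_ref, 1=het, 2=hom_alt, 3=unknown
_FROM_GTS012 = np.array([HOM_REF, HET, HOM_ALT, MISSING], dtype=np.int8)

_INFO_HEADER = [
    ("QD", "1", "Float", "Variant confidence normalized by depth"),
    ("FS", "1", "Float", "Phred-scaled strand-bias Fisher exact test P"),
    ("MQ", "1", "Float", "RMS mapping quality"),
    ("MQRankSum", "1", "Float", "Mapping-quality rank-sum test Z-score"),
    ("ReadPosRankSum", "1", "Float", "Read-position rank-sum test Z-score"),
    ("DP", "1", "Integer", "Combined read depth across samples"),
    ("DELETERIOUS", "0", "Flag", "Variant annotated as deleterious by an external predictor"),
]


def _fmt(x: float) -> str:
    if float(x) == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.4f}".rstrip("0").rstrip(".")


def write_vcf(callset: CohortCallset, path: str) -> None:
    """Write a call set as an uncompressed VCF 4.2 text file."""
    info = callset.info
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=vitivar\n")
        for c in pd.unique(callset.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        for key, num, typ, desc in _INFO_HEADER:
            fh.write(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(callset.samples) + "\n")
        for i in range(callset.n_sites):
            parts = []
            for key in INFO_FIELDS:
                v = info.iloc[i][key]
                if np.isfinite(v):
                    parts.append(f"{key}={_fmt(float(v))}")
            if callset.deleterious[i]:
                parts.append("DELETERIOUS")
            info_str = ";".join(parts) if parts else "."
            qual = "." if not np.isfinite(callset.qual[i]) else _fmt(float(callset.qual[i]))
            cols = [
                str(callset.chrom[i]),
                str(callset.pos[i]),
                ".",
                str(callset.ref[i]),
                str(callset.alt[i]),
                qual,
                ".",
                info_str,
                "GT:AD:DP",
            ]
            for s in range(callset.n_samples):
                g = _GT_STR[int(callset.gt[i, s])]
                cols.append(
                    f"{g}:{callset.ad_ref[i, s]},{callset.ad_alt[i, s]}:{callset.dp[i, s]}"
                )
            fh.write("\t".join(cols) + "\n")


def read_vcf(path: str) -> CohortCallset:
    """Read a VCF into a :class:`CohortCallset`.

    Multi-allelic records are kept (ALT comma-joined) so that biallelic
    selection can be exercised downstream; their AD is truncated to the
    reference and first alternate allele.
    """
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    chrom, pos, ref, alt, qual = [], [], [], [], []
    info_rows, gt_rows, adr_rows, ada_rows, dp_rows, dele = [], [], [], [], [], []
    for v in vcf:
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(",".join(v.ALT) if v.ALT else ".")
        qual.append(np.nan if v.QUAL is None else float(v.QUAL))
        info_rows.append(
            [np.nan if v.INFO.get(k) is None else float(v.INFO.get(k)) for k in INFO_FIELDS]
        )
        dele.append(v.INFO.get("DELETERIOUS") is not None)
        gt_rows.append(_FROM_GTS012[np.asarray(v.gt_types, dtype=np.int64)])
        ad = v.format("AD")
        if ad is None:
            adr = np.zeros(len(samples), dtype=np.int32)
            ada = np.zeros(len(samples), dtype=np.int32)
        else:
            ad = np.asarray(ad, dtype=np.int64)
            adr = np.clip(ad[:, 0], 0, None).astype(np.int32)
            ada = (
                np.clip(ad[:, 1], 0, None).astype(np.int32)
                if ad.shape[1] > 1
                else np.zeros(len(samples), dtype=np.int32)
            )
        dparr = v.format("DP")
        if dparr is None:
            dpv = adr + ada
        else:
            dpv = np.clip(np.asarray(dparr, dtype=np.int64)[:, 0], 0, None).astype(np.int32)
        adr_rows.append(adr)
        ada_rows.append(ada)
        dp_rows.append(dpv)
    vcf.close()
    n = len(pos)
    ns = len(samples)

    def stack(rows, dtype):
        if n == 0:
            return np.zeros((0, ns), dtype=dtype)
        return np.vstack(rows).astype(dtype)

    return CohortCallset(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        qual=np.array(qual, dtype=float),
        info=pd.DataFrame(info_rows, columns=list(INFO_FIELDS), dtype=float)
        if n
        else pd.DataFrame(columns=list(INFO_FIELDS), dtype=float),
        gt=stack(gt_rows, np.int8),
        ad_ref=stack(adr_rows, np.int32),
        ad_alt=stack(ada_rows, np.int32),
        dp=stack(dp_rows, np.int32),
        samples=samples,
        deleterious=np.array(dele, dtype=bool),
    )


def write_metadata(metadata: pd.DataFrame, path: str) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata(path: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str, "phenotype": str})
    required = {"sample", "group", "phenotype", "mean_depth"}
    if not required.issubset(frame.columns):
        raise DataError(f"metadata table must have columns {sorted(required)}")
    return frame


def write_bed(intervals: pd.DataFrame, path: str) -> None:
    """Write (chrom, start, end) intervals as BED (0-based half-open)."""
    intervals[["chrom", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str) -> pd.DataFrame:
    if os.path.getsize(path) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    frame = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2])
    frame.columns = ["chrom", "start", "end"]
    return frame


def write_truth(truth: "TruthSet", path: str) -> None:
    """Serialize a truth set as a TSV genotype matrix with a JSON header
    comment carrying the trait model and phenotypes."""
    meta = {
        "dominant_locus": truth.trait_model.dominant_locus,
        "recessive_loci": list(truth.trait_model.recessive_loci),
        "min_recessive_hom": truth.trait_model.min_recessive_hom,
        "phenotypes": dict(truth.true_phenotypes),
    }
    with open(path, "w") as fh:
        fh.write("#vitivar_truth " + json.dumps(meta, sort_keys=True) + "\n")
        fh.write("chrom\tpos\tref\talt\t" + "\t".join(truth.samples) + "\n")
        for i in range(len(truth.pos)):
            row = [str(truth.chrom[i]), str(truth.pos[i]), str(truth.ref[i]), str(truth.alt[i])]
            row += [_GT_STR[int(g)] for g in truth.true_genotypes[i]]
            fh.write("\t".join(row) + "\n")


def read_truth(path: str) -> "TruthSet":
    from .seedless import TraitModel
    from .simulate import TruthSet

    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#vitivar_truth "):
            raise DataError("not a vitivar truth table")
        meta = json.loads(header[len("#vitivar_truth ") :])
        frame = pd.read_csv(fh, sep="\t")
    samples = list(frame.columns[4:])
    inv = {v: k for k, v in _GT_STR.items()}
    gt = np.array(
        [[inv[g] for g in frame[s]] for s in samples], dtype=np.int8
    ).T if samples else np.zeros((len(frame), 0), dtype=np.int8)
    model = TraitModel(
        dominant_locus=meta["dominant_locus"],
        recessive_loci=tuple(meta["recessive_loci"]),
        min_recessive_hom=int(meta["min_recessive_hom"]),
    )
    return TruthSet(
        chrom=frame["chrom"].to_numpy(dtype=object),
        pos=frame["pos"].to_numpy(dtype=np.int64),
        ref=frame["ref"].to_numpy(dtype=object),
        alt=frame["alt"].to_numpy(dtype=object),
        true_genotypes=gt,
        samples=samples,
        trait_model=model,
        repeat_intervals=pd.DataFrame(columns=["chrom", "start", "end"]),
        true_phenotypes=dict(meta["phenotypes"]),
    )
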