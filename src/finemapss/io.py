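"""Readers and writers for the package's text interchange formats.

Summary TSV: tab-delimited with a header; columns ``snp``, ``a1``, ``a2``,
then either ``betahat`` + ``se`` or ``z``.  LD matrices: dense
whitespace-delimited J x J text, or an HDF5 container with datasets ``R``
and (optionally) ``snp`` giving the row order.  Row/column order of the
LD matrix must match the summary TSV; when SNP ids are available in both,
the order is validated rather than silently reindexed.  SNPs present in
the summary file but absent from the LD matrix are an error, never a
silent subset.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._exceptions import InputError
from .cs import CredibleSet
from .sufficient import LDMatrix, SummaryData

__all__ = [
    "read_summary_tsv",
    "write_summary_tsv",
    "read_ld_matrix",
    "write_ld_matrix",
    "write_cs_report",
    "read_matrix_text",
]


def read_summary_tsv(path: Union[str, Path]) -> SummaryData:
    """Parse a summary TSV into :class:`SummaryData`."""
    df = pd.read_csv(path, sep="\t")
    cols = set(df.columns)
    if "snp" not in cols:
        raise InputError(f"{path}: summary TSV must have a 'snp' column")
    has_effects = {"betahat", "se"} <= cols
    has_z = "z" in cols
    if not has_effects and not has_z:
        raise InputError(
            f"{path}: summary TSV needs either 'betahat'+'se' or 'z' columns"
        )
    for col in ("betahat", "se", "z"):
        if col in cols and df[col].isna().any():
            bad = df.loc[df[col].isna(), "snp"].iloc[0]
            raise InputError(
                f"{path}: missing {col!r} value for SNP {bad!r}; remove the "
                "SNP or supply the statistic (imputation is out of scope)"
            )
    return SummaryData(
        snp_ids=df["snp"].astype(str).tolist(),
        bhat=df["betahat"].to_numpy(float) if has_effects else None,
        shat=df["se"].to_numpy(float) if has_effects else None,
        zhat=df["z"].to_numpy(float) if has_z else None,
        ref_allele=df["a1"].astype(str).tolist() if "a1" in cols else None,
        alt_allele=df["a2"].astype(str).tolist() if "a2" in cols else None,
    )


def write_summary_tsv(sd: SummaryData, path: Union[str, Path]) -> None:
    df = pd.DataFrame({"snp": sd.snp_ids})
    df["a1"] = sd.ref_allele if sd.ref_allele is not None else "A"
    df["a2"] = sd.alt_allele if sd.alt_allele is not None else "G"
    if sd.bhat is not None and sd.shat is not None:
        df["betahat"] = sd.bhat
        df["se"] = sd.shat
    if sd.zhat is not None:
        df["z"] = sd.zhat
    df.to_csv(path, sep="\t", index=False)


def read_matrix_text(path: Union[str, Path]) -> np.ndarray:
    """Dense whitespace-delimited numeric matrix."""
    M = np.loadtxt(path)
    if M.ndim == 0:
        M = M.reshape(1, 1)
    elif M.ndim == 1:
        M = M.reshape(1, -1) if M.size > 1 else M.reshape(1, 1)
    return M


def read_ld_matrix(
    path: Union[str, Path],
    snp_ids: Optional[Sequence[str]] = None,
    source: str = "reference_panel",
) -> LDMatrix:
    """Read an LD matrix from text or an HDF5 container.

    HDF5 files (suffix .h5 / .hdf5) must carry a ``R`` dataset and may
    carry a ``snp`` dataset with the row ordering; when both that and
    ``snp_ids`` are given, the orders must agree exactly.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            if "R" not in f:
                raise InputError(f"{path}: HDF5 LD container must have dataset 'R'")
            R = np.asarray(f["R"], dtype=float)
            file_ids = None
            if "snp" in f:
                file_ids = [
                    s.decode() if isinstance(s, bytes) else str(s)
                    for s in f["snp"][()]
                ]
        if snp_ids is not None and file_ids is not None:
            if list(snp_ids) != file_ids:
                raise InputError(
                    f"{path}: LD matrix SNP order does not match the summary TSV"
                )
    else:
        R = read_matrix_text(path)
    if snp_ids is not None and R.shape[0] != len(snp_ids):
        raise InputError(
            f"{path}: LD matrix has dimension {R.shape[0]} but the summary "
            f"TSV lists {len(snp_ids)} SNPs"
        )
    return LDMatrix(R=R, source=source)


def write_ld_matrix(R: LDMatrix, path: Union[str, Path]) -> None:
    np.savetxt(path, R.R, fmt="%.10g")


def write_cs_report(
    sets: Sequence[CredibleSet],
    snp_ids: Sequence[str],
    path: Union[str, Path],
) -> None:
    """Credible-set report TSV: one row per set."""
    rows = []
    for k, cs_ in enumerate(sets, start=1):
        rows.append({
            "cs_id": k,
            "effect": cs_.effect_index + 1,
            "coverage": f"{cs_.coverage_attained:.6g}",
            "purity": f"{cs_.purity:.6g}",
            "n_snps": len(cs_),
            "snps": ",".join(snp_ids[i] for i in cs_.snp_indices),
        })
    pd.DataFrame(
        rows, columns=["cs_id", "effect", "coverage", "purity", "n_snps", "snps"]
    ).to_csv(path, sep="\t", index=False)
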