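"""Tab-separated interchange formats and the truth JSON.

All tables are UTF-8 TSV with a header row and ``NA`` as the missing-value
token.  Readers validate structure (headers, value domains, sortedness,
duplicate ids) and report the offending row/column on failure, so malformed
inputs fail loudly at the boundary instead of deep inside an analysis.

Formats
-------
panel       marker, chrom, pos_bp, cM, <one 0/1 column per founder>
genotypes   animal, <one column per marker>; values 0/1/2/NA
phenotypes  animal, <one column per trait>; floats, NA allowed
expression  gene, <one column per animal>; nonnegative counts
dosage      animal, <one column per marker>; floats in [0, 2]
kinship     id, <one column per id>; symmetric floats
scan        marker, chrom, pos_bp, logP
intervals   trait, chrom, peak_marker, start_bp, end_bp, peak_logp, threshold, r2_min
mediation   output of :func:`hsqtl.mediation.mediate`
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from hsqtl.hmm import MISSING, FounderPanel
from hsqtl.scan import QTLInterval

__all__ = [
    "write_panel", "read_panel",
    "write_genotypes", "read_genotypes",
    "write_phenotypes", "read_phenotypes",
    "write_expression", "read_expression",
    "write_dosage_matrix", "read_dosage_matrix",
    "write_kinship", "read_kinship",
    "write_scan", "read_scan",
    "write_intervals", "read_intervals",
    "write_truth_json", "read_truth_json",
    "read_vcf_genotypes",
    "write_diplotype_probs_npz", "read_diplotype_probs_npz",
]

_RESERVED_META = ("marker", "chrom", "pos_bp", "cM")


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", na_values=["NA"], keep_default_na=False,
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV ({exc})") from exc
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype(str)  # chromosome names are labels
    return df


# -- founder panel ----------------------------------------------------------


def write_panel(path, panel: FounderPanel) -> None:
    df = panel.markers[["marker", "chrom", "pos_bp", "cM"]].copy()
    for i, name in enumerate(panel.founders):
        df[name] = panel.alleles[i]
    df.to_csv(path, sep="\t", index=False)


def read_panel(path) -> FounderPanel:
    df = _read_tsv(path)
    for col in _RESERVED_META:
        if col not in df.columns:
            raise ValueError(f"{path}: panel header missing column {col!r}")
    founders = [c for c in df.columns if c not in _RESERVED_META]
    if not founders:
        raise ValueError(f"{path}: no founder allele columns")
    if df["marker"].duplicated().any():
        dup = df["marker"][df["marker"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated marker id {dup!r}")
    alleles = df[founders].to_numpy()
    bad = ~np.isin(alleles, [0, 1])
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid founder allele {alleles[r, c]!r} at marker "
            f"{df['marker'].iloc[r]!r}, founder {founders[c]!r}"
        )
    markers = df[list(_RESERVED_META)].copy()
    try:
        return FounderPanel(founders=founders, markers=markers, alleles=alleles.T.astype(np.int8))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


# -- genotypes --------------------------------------------------------------


def write_genotypes(path, genotypes: np.ndarray, animals: list[str], markers: list[str]) -> None:
    geno = np.asarray(genotypes)
    df = pd.DataFrame(geno.astype(object), index=animals, columns=markers)
    df = df.where(geno != MISSING, other="NA")
    df.index.name = "animal"
    df.to_csv(path, sep="\t")


def read_genotypes(path) -> tuple[np.ndarray, list[str], list[str]]:
    df = _read_tsv(path)
    if df.columns[0] != "animal":
        raise ValueError(f"{path}: first genotype column must be 'animal'")
    animals = df["animal"].astype(str).tolist()
    if len(set(animals)) != len(animals):
        dup = pd.Series(animals)[pd.Series(animals).duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated animal id {dup!r}")
    markers = list(df.columns[1:])
    vals = df[markers].to_numpy(dtype=float)
    finite = vals[~np.isnan(vals)]
    bad = ~np.isin(finite, [0.0, 1.0, 2.0])
    if bad.any():
        mask = ~np.isnan(vals) & ~np.isin(vals, [0.0, 1.0, 2.0])
        r, c = np.argwhere(mask)[0]
        raise ValueError(
            f"{path}: invalid genotype {vals[r, c]:g} for animal {animals[r]!r}, "
            f"marker {markers[c]!r} (must be 0/1/2/NA)"
        )
    geno = np.where(np.isnan(vals), MISSING, vals).astype(np.int8)
    return geno, animals, markers


# -- phenotypes / expression ------------------------------------------------


def write_phenotypes(path, phenotypes: pd.DataFrame) -> None:
    df = phenotypes.copy()
    if "animal" not in df.columns:
        df = df.reset_index().rename(columns={"index": "animal"})
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if "animal" not in df.columns:
        raise ValueError(f"{path}: phenotype table needs an 'animal' column")
    if df["animal"].duplicated().any():
        dup = df["animal"][df["animal"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated animal id {dup!r}")
    return df


def write_expression(path, counts: pd.DataFrame) -> None:
    df = counts.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_expression(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if df.columns[0] != "gene":
        raise ValueError(f"{path}: first expression column must be 'gene'")
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated gene id {dup!r}")
    out = df.set_index("gene")
    vals = out.to_numpy(dtype=float)
    if (vals[~np.isnan(vals)] < 0).any():
        mask = ~np.isnan(vals) & (vals < 0)
        r, c = np.argwhere(mask)[0]
        raise ValueError(
            f"{path}: negative expression value at gene {out.index[r]!r}, "
            f"sample {out.columns[c]!r}"
        )
    return out


# -- dosage / kinship -------------------------------------------------------


def write_dosage_matrix(path, doses: np.ndarray, animals: list[str], markers: list[str]) -> None:
    df = pd.DataFrame(np.asarray(doses, dtype=float), index=animals, columns=markers)
    df.index.name = "animal"
    df.to_csv(path, sep="\t")


def read_dosage_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    df = _read_tsv(path)
    if df.columns[0] != "animal":
        raise ValueError(f"{path}: first dosage column must be 'animal'")
    animals = df["animal"].astype(str).tolist()
    markers = list(df.columns[1:])
    vals = df[markers].to_numpy(dtype=float)
    if ((vals < -1e-9) | (vals > 2 + 1e-9)).any():
        r, c = np.argwhere((vals < -1e-9) | (vals > 2 + 1e-9))[0]
        raise ValueError(
            f"{path}: dose {vals[r, c]:g} outside [0, 2] for animal "
            f"{animals[r]!r}, marker {markers[c]!r}"
        )
    return vals, animals, markers


def write_kinship(path, K: np.ndarray, ids: list[str]) -> None:
    df = pd.DataFrame(np.asarray(K, dtype=float), index=ids, columns=ids)
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def read_kinship(path) -> tuple[np.ndarray, list[str]]:
    df = _read_tsv(path)
    if df.columns[0] != "id":
        raise ValueError(f"{path}: first kinship column must be 'id'")
    ids = df["id"].astype(str).tolist()
    K = df[df.columns[1:]].to_numpy(dtype=float)
    if K.shape[0] != K.shape[1] or list(df.columns[1:]) != ids:
        raise ValueError(f"{path}: kinship row/column ids do not match")
    return K, ids


# -- scan / intervals -------------------------------------------------------


def write_scan(path, table: pd.DataFrame) -> None:
    table[["marker", "chrom", "pos_bp", "logP"]].to_csv(path, sep="\t", index=False)


def read_scan(path) -> pd.DataFrame:
    df = _read_tsv(path)
    need = {"marker", "chrom", "pos_bp", "logP"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: scan table missing {sorted(need - set(df.columns))}")
    return df


def write_intervals(path, intervals: list[QTLInterval]) -> None:
    rows = [iv.to_dict() for iv in intervals]
    pd.DataFrame(
        rows,
        columns=["trait", "chrom", "peak_marker", "start_bp", "end_bp",
                 "peak_logp", "threshold", "r2_min"],
    ).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_intervals(path) -> pd.DataFrame:
    return _read_tsv(path)


# -- truth JSON -------------------------------------------------------------


def write_truth_json(path, truth: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True, default=default)


def read_truth_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# -- VCF convenience import -------------------------------------------------


def read_vcf_genotypes(path) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """GT-only import of an (uncompressed) VCF v4.2 into the genotype codes.

    Returns ``(genotypes, sample_ids, marker_table)`` where genotypes count
    ALT alleles (0/1/2, -1 for missing); phasing is ignored.  Multiallelic
    records are rejected.
    """
    samples: list[str] = []
    rows = []
    geno_rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise ValueError(f"{path}:{lineno}: VCF has no sample columns")
                samples = fields[9:]
                continue
            if not samples:
                raise ValueError(f"{path}:{lineno}: data line before #CHROM header")
            fields = line.split("\t")
            chrom, pos, vid, _ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                raise ValueError(f"{path}:{lineno}: multiallelic record not supported")
            fmt = fields[8].split(":")
            if "GT" not in fmt:
                raise ValueError(f"{path}:{lineno}: record lacks GT field")
            gt_i = fmt.index("GT")
            calls = []
            for si, sample in enumerate(fields[9:]):
                gt = sample.split(":")[gt_i].replace("|", "/")
                if gt in (".", "./."):
                    calls.append(MISSING)
                    continue
                try:
                    a, b = (int(x) for x in gt.split("/"))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: bad GT {gt!r} for sample {samples[si]!r}"
                    ) from exc
                calls.append(a + b)
            rows.append((vid if vid != "." else f"{chrom}:{pos}", chrom, int(pos)))
            geno_rows.append(calls)
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "pos_bp"])
    geno = np.asarray(geno_rows, dtype=np.int8).T  # samples x markers
    return geno, samples, markers


# -- diplotype posterior sidecar --------------------------------------------


def write_diplotype_probs_npz(path, probs) -> None:
    """Optional binary sidecar for diplotype posteriors.

    Layout (``numpy.savez_compressed``): ``probs`` is the
    ``(n_animals, n_markers, n_states)`` float64 posterior array, ``states``
    an ``(n_states, 2)`` int array of founder-index pairs in canonical
    order, ``animals`` the animal ids (or an empty array), and
    ``log_likelihood`` the per-animal total log-likelihood.
    """
    np.savez_compressed(
        path,
        probs=probs.probs,
        states=np.asarray(probs.states, dtype=np.int64),
        animals=np.asarray(probs.animals if probs.animals is not None else [], dtype=object),
        log_likelihood=(
            probs.log_likelihood if probs.log_likelihood is not None else np.empty(0)
        ),
    )


def read_diplotype_probs_npz(path):
    from hsqtl.hmm import DiplotypeProbs

    with np.load(path, allow_pickle=True) as dat:
        animals = dat["animals"].tolist() or None
        ll = dat["log_likelihood"]
        return DiplotypeProbs(
            states=[tuple(s) for s in dat["states"]],
            probs=dat["probs"],
            animals=animals,
            log_likelihood=ll if ll.size else None,
        )
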