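"""Delimited-text schemas and readers/writers.

All tables are comma-delimited UTF-8 with '.' decimals.  Every file starts
with a header block of ``# key: value`` lines carrying at least the
package version and, where applicable, the RNG seed, the distance metric
and a hash of the run configuration.  Years are integers; the missing
genotype token is ``NA``; locus and colony identifiers are 1-based
strings in files (0-based indices are internal only).
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import SchemaError
from .types import (
    MISSING,
    ClusterAlleleFreqs,
    ColonyMap,
    GenotypeDataset,
    GrowthForcing,
    MetapopTrajectory,
    circular_distance_matrix,
    haversine_distance_matrix,
)

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(meta: dict) -> str:
    lines = [f"# version: {__version__}"]
    for k, v in meta.items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def _atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a tidy table with a ``# key: value`` header block, atomically."""
    buf = _io.StringIO()
    buf.write(_header_lines(meta or {}))
    # %.17g guarantees exact binary round-trip of doubles through text
    df.to_csv(buf, index=False, na_rep=MISSING_TOKEN, float_format="%.17g")
    _atomic_write(path, buf.getvalue())


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a tidy table, returning the frame and the parsed header block."""
    meta: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(
        path,
        comment="#",
        na_values=[MISSING_TOKEN],
        keep_default_na=False,
        float_precision="round_trip",
    )
    return df, meta


# ---------------------------------------------------------------- colony map

COLONY_COLUMNS = {"colony_id", "region", "K", "n0"}


def write_colony_table(cmap: ColonyMap, path: str | Path, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "colony_id": cmap.ids,
            "name": cmap.ids,
            "region": cmap.region,
            "K": cmap.K,
            "n0": cmap.n0,
        }
    )
    meta = dict(meta or {})
    meta["metric"] = cmap.metric
    if cmap.metric == "circular":
        df.insert(2, "arc_km", cmap.coords["arc_km"])
        meta["circumference_km"] = cmap.coords["circumference_km"]
    else:
        df.insert(2, "lon", cmap.coords["lon"])
        df.insert(3, "lat", cmap.coords["lat"])
    write_table(df, path, meta)


def read_colony_table(path: str | Path) -> ColonyMap:
    """Read and validate a colony table; builds the distance matrix.

    An ``arc_km`` column selects the circular (shorter-arc) metric, using
    the ``circumference_km`` header entry; ``lon``/``lat`` columns select
    the haversine great-circle metric.
    """
    df, meta = read_table(path)
    missing = COLONY_COLUMNS - set(df.columns)
    if missing:
        raise SchemaError(f"colony table missing columns: {sorted(missing)}")
    dup = df["colony_id"][df["colony_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"duplicate colony_id values: {sorted(set(dup.astype(str)))}")
    if (df["K"] <= 0).any():
        bad = df.loc[df["K"] <= 0, "colony_id"].tolist()
        raise SchemaError(f"non-positive carrying capacity for colonies: {bad}")
    ids = df["colony_id"].astype(str).tolist()
    if "arc_km" in df.columns:
        if "circumference_km" not in meta:
            raise SchemaError(
                "arc_km column requires a '# circumference_km:' header entry"
            )
        circ = float(meta["circumference_km"])
        arc = df["arc_km"].to_numpy(float)
        dist = circular_distance_matrix(arc, circ)
        metric = "circular"
        coords = {"arc_km": arc, "circumference_km": circ}
    elif {"lon", "lat"} <= set(df.columns):
        lon = df["lon"].to_numpy(float)
        lat = df["lat"].to_numpy(float)
        dist = haversine_distance_matrix(lon, lat)
        metric = "haversine"
        coords = {"lon": lon, "lat": lat}
    else:
        raise SchemaError("colony table needs either arc_km or lon/lat columns")
    return ColonyMap(
        ids=ids,
        region=df["region"].to_numpy(object),
        K=df["K"].to_numpy(float),
        n0=df["n0"].to_numpy(float),
        dist=dist,
        metric=metric,
        coords=coords,
    )


# ------------------------------------------------------------------- forcing


def write_forcing(forcing: GrowthForcing, colony_ids: list[str], path: str | Path, meta: dict | None = None) -> None:
    meta = dict(meta or {})
    meta["rc_star"] = repr(forcing.rc_star)
    df = pd.DataFrame(forcing.r, columns=[str(y) for y in forcing.years])
    df.insert(0, "colony_id", colony_ids)
    write_table(df, path, meta)


def read_forcing(path: str | Path) -> tuple[GrowthForcing, list[str]]:
    df, meta = read_table(path)
    if "colony_id" not in df.columns:
        raise SchemaError("forcing table missing colony_id column")
    year_cols = [c for c in df.columns if c != "colony_id"]
    try:
        years = np.array([int(c) for c in year_cols])
    except ValueError as exc:
        raise SchemaError(f"forcing columns must be years: {exc}") from exc
    rc_star = float(meta["rc_star"]) if "rc_star" in meta else None
    forcing = GrowthForcing(
        years=years, r=df[year_cols].to_numpy(float), rc_star=rc_star
    )
    return forcing, df["colony_id"].astype(str).tolist()


# ----------------------------------------------------------------- genotypes


def write_genotypes(data: GenotypeDataset, path: str | Path, meta: dict | None = None) -> None:
    """Long-format genotype table: individual_id, colony_id, year, locus_id, code."""
    n, L = data.codes.shape
    codes = data.codes.astype(object)
    codes[codes == MISSING] = None
    df = pd.DataFrame(
        {
            "individual_id": np.repeat(data.individual_ids, L),
            "colony_id": np.repeat(data.colony_ids, L),
            "year": np.repeat(data.years, L),
            "locus_id": np.tile(data.locus_ids, n),
            "code": codes.ravel(),
        }
    )
    write_table(df, path, meta)


def read_genotypes(path: str | Path, known_colonies: list[str] | None = None) -> GenotypeDataset:
    """Read a long-format genotype table into the wide internal layout."""
    df, _ = read_table(path)
    required = {"individual_id", "colony_id", "year", "locus_id", "code"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"genotype table missing columns: {sorted(missing)}")
    if known_colonies is not None:
        unknown = set(df["colony_id"].astype(str)) - set(known_colonies)
        if unknown:
            raise SchemaError(f"unknown colony_id values: {sorted(unknown)}")
    codes = df["code"]
    bad = codes.dropna()[~codes.dropna().isin([0, 1, 2])]
    if len(bad):
        raise SchemaError(f"genotype codes outside {{0,1,2,NA}}: {sorted(set(bad))}")
    ind_ids = list(dict.fromkeys(df["individual_id"].astype(str)))
    locus_ids = list(dict.fromkeys(df["locus_id"].astype(str)))
    ind_pos = {v: i for i, v in enumerate(ind_ids)}
    loc_pos = {v: i for i, v in enumerate(locus_ids)}
    wide = np.full((len(ind_ids), len(locus_ids)), MISSING, dtype=np.int8)
    rows = df["individual_id"].astype(str).map(ind_pos).to_numpy()
    cols = df["locus_id"].astype(str).map(loc_pos).to_numpy()
    vals = codes.fillna(MISSING).to_numpy(dtype=np.int8)
    wide[rows, cols] = vals
    prov = df.drop_duplicates("individual_id").set_index(
        df.drop_duplicates("individual_id")["individual_id"].astype(str)
    )
    colony = np.array([str(prov.loc[i, "colony_id"]) for i in ind_ids], dtype=object)
    years = np.array([int(prov.loc[i, "year"]) for i in ind_ids])
    return GenotypeDataset(
        individual_ids=ind_ids,
        colony_ids=colony,
        years=years,
        locus_ids=locus_ids,
        codes=wide,
    )


def read_genotypes_vcf(
    vcf_path: str | Path, samples_path: str | Path
) -> tuple[GenotypeDataset, int]:
    """Ingest biallelic SNPs from a VCF plus a sample-provenance table.

    ``samples_path`` is a delimited table with columns individual_id,
    colony_id, year covering every VCF sample.  Codes count copies of the
    REF allele; multi-allelic records are skipped and their count is
    returned alongside the dataset.
    """
    from cyvcf2 import VCF

    sdf, _ = read_table(samples_path)
    required = {"individual_id", "colony_id", "year"}
    if not required <= set(sdf.columns):
        raise SchemaError(f"sample table needs columns {sorted(required)}")
    sdf = sdf.set_index(sdf["individual_id"].astype(str))
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    unknown = set(samples) - set(sdf.index)
    if unknown:
        raise SchemaError(f"VCF samples missing from sample table: {sorted(unknown)}")
    locus_ids: list[str] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(rec.gt_types)
        code = np.select(
            [gt == 0, gt == 1, gt == 3], [2, 1, 0], default=MISSING
        ).astype(np.int8)
        rows.append(code)
        locus_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
    if skipped:
        logger.info("skipped %d multi-allelic VCF records", skipped)
    codes = (
        np.vstack(rows).T if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    data = GenotypeDataset(
        individual_ids=samples,
        colony_ids=np.array([str(sdf.loc[s, "colony_id"]) for s in samples], dtype=object),
        years=np.array([int(sdf.loc[s, "year"]) for s in samples]),
        locus_ids=locus_ids,
        codes=codes,
    )
    return data, skipped


# ----------------------------------------------------------- frequency table


def write_freqs(freqs: ClusterAlleleFreqs, path: str | Path, meta: dict | None = None) -> None:
    df = pd.DataFrame(freqs.p.T, columns=freqs.clusters)
    df.insert(0, "locus_id", freqs.locus_ids)
    write_table(df, path, meta)


def read_freqs(path: str | Path) -> ClusterAlleleFreqs:
    df, _ = read_table(path)
    if "locus_id" not in df.columns:
        raise SchemaError("frequency table missing locus_id column")
    clusters = [c for c in df.columns if c != "locus_id"]
    return ClusterAlleleFreqs(
        clusters=clusters,
        locus_ids=df["locus_id"].astype(str).tolist(),
        p=df[clusters].to_numpy(float).T,
    )


# --------------------------------------------------------------- trajectories


def write_trajectory(traj: MetapopTrajectory, path: str | Path, meta: dict | None = None) -> None:
    write_table(traj.to_frame(), path, meta)


def read_trajectory(path: str | Path) -> tuple[pd.DataFrame, dict]:
    return read_table(path)


# ----------------------------------------------------------------- fit report


def write_fit_report(report, path: str | Path, meta: dict | None = None) -> None:
    """Serialize a FitReport as a key-value header plus a DIC table."""
    meta = dict(meta or {})
    meta["selected_behavior"] = report.selected.value
    lines = [_header_lines(meta)]
    lines.append("behavior,dic,ess\n")
    for b, v in report.dic.items():
        ess = report.samples[b].ess if b in report.samples else float("nan")
        lines.append(f"{b.value},{v},{ess}\n")
    if report.notes:
        lines.append("# " + "; ".join(report.notes) + "\n")
    _atomic_write(path, "".join(lines))
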