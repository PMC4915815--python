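"""Readers and writers for the standard formats touched by the pipeline.

Haplotypes move as IMPUTE2-style .haps/.sample pairs or phased VCF;
recombination maps as HapMap-style text (position, rate cM/Mb, cumulative
cM); results as TSV/JSON with a run manifest carrying the configuration,
seed and package version for reproducibility.  Coordinates are 0-based
half-open internally and 1-based at the VCF boundary.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genmap import GeneticMap
from .globetrotter import AdmixtureEvent
from .panel import HaplotypePanel

__all__ = [
    "read_haps",
    "write_haps",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_genetic_map",
    "write_genetic_map",
    "write_results",
    "event_to_dict",
    "event_from_dict",
]


# ----------------------------------------------------------- haps/sample

def write_haps(panel: HaplotypePanel, haps_path, sample_path, maps=None) -> None:
    """Write a panel as an IMPUTE2-style .haps/.sample pair."""
    with open(haps_path, "w") as fh:
        for s in range(panel.n_sites):
            alleles = " ".join(str(int(a)) for a in panel.haps[:, s])
            fh.write(
                f"{panel.chrom[s]} snp{s} {int(panel.positions[s]) + 1} A G {alleles}\n"
            )
    with open(sample_path, "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        groups = panel.groups
        for i, sid in enumerate(panel.sample_ids):
            g = groups[2 * i] if 2 * len(panel.sample_ids) == panel.n_hap else groups[i]
            fh.write(f"{sid} {g} 0\n")


def read_haps(haps_path, sample_path, maps=None) -> HaplotypePanel:
    """Read an IMPUTE2-style .haps/.sample pair.

    ``maps`` (GeneticMap list, keyed by chromosome label) supplies genetic
    coordinates; without it cM defaults to 1 cM/Mb.
    """
    chroms, positions, rows = [], [], []
    with open(haps_path) as fh:
        for line in fh:
            parts = line.split()
            chroms.append(parts[0])
            positions.append(int(parts[2]) - 1)
            rows.append([int(a) for a in parts[5:]])
    haps = np.array(rows, dtype=np.uint8).T
    chrom = np.array(chroms)
    positions = np.array(positions, dtype=np.int64)
    sample_ids, groups = [], []
    with open(sample_path) as fh:
        lines = fh.read().splitlines()[2:]
    for line in lines:
        parts = line.split()
        sample_ids.append(parts[0])
        groups.extend([parts[1], parts[1]])
    cm = _cm_for_sites(chrom, positions, maps)
    return HaplotypePanel(
        haps=haps, positions=positions, chrom=chrom, cm=cm,
        sample_ids=sample_ids, groups=np.array(groups[: haps.shape[0]]),
    )


def _cm_for_sites(chrom, positions, maps) -> np.ndarray:
    if maps is None:
        return positions / 1e6  # 1 cM/Mb fallback
    by_label = {str(m.chrom): m for m in maps}
    cm = np.empty(positions.size)
    for c in np.unique(chrom):
        if str(c) not in by_label:
            raise ValueError(f"no genetic map for chromosome {c}")
        sel = chrom == c
        cm[sel] = by_label[str(c)].interp_cm(positions[sel])
    return cm


# ------------------------------------------------------------------- VCF

def write_phased_vcf(panel: HaplotypePanel, path) -> None:
    """Write a panel as a minimal phased VCF (text, '|' separators)."""
    if panel.n_hap % 2:
        raise ValueError("VCF output requires diploid individuals")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids) + "\n"
        )
        for s in range(panel.n_sites):
            gts = "\t".join(
                f"{panel.haps[2 * i, s]}|{panel.haps[2 * i + 1, s]}"
                for i in range(len(panel.sample_ids))
            )
            fh.write(
                f"{panel.chrom[s]}\t{int(panel.positions[s]) + 1}\tsnp{s}\t"
                f"A\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_phased_vcf(path, maps=None, groups=None) -> HaplotypePanel:
    """Read phased biallelic records from a VCF.

    Unphased records ('/' separator) are rejected, naming the first
    offending record; multi-allelic sites are skipped with a count.
    ``groups`` optionally maps sample id to group label.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, positions, rows = [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        gts = var.genotypes  # [a0, a1, phased]
        for g in gts:
            if len(g) >= 3 and not g[2]:
                raise ValueError(
                    f"unphased genotype at {var.CHROM}:{var.POS} "
                    "(phased VCF required, '|' separator)"
                )
        chroms.append(var.CHROM)
        positions.append(var.POS - 1)
        rows.append([a for g in gts for a in g[:2]])
    if n_skipped:
        import warnings

        warnings.warn(f"skipped {n_skipped} multi-allelic site(s)")
    haps = np.array(rows, dtype=np.uint8).T
    chrom = np.array(chroms)
    positions = np.array(positions, dtype=np.int64)
    cm = _cm_for_sites(chrom, positions, maps)
    grp = np.array(
        [groups.get(s, s) if groups else s for s in samples for _ in range(2)]
    )
    return HaplotypePanel(
        haps=haps, positions=positions, chrom=chrom, cm=cm,
        sample_ids=samples, groups=grp,
    )


# ------------------------------------------------------------------ maps

def read_genetic_map(path, chrom: str | None = None) -> GeneticMap:
    """Read a HapMap-style recombination map.

    Expects whitespace-delimited columns: position(bp), rate(cM/Mb), and
    optionally cumulative cM (used when present, integrated from the rate
    otherwise).  A header row is detected and skipped.  Decreasing
    cumulative cM or unsorted positions are rejected.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    try:
        float(df.iloc[0, 0])
    except ValueError:
        df = df.iloc[1:]
    pos = df.iloc[:, 0].astype(float).to_numpy()
    if np.any(np.diff(pos) <= 0):
        raise ValueError("map rows are not sorted by increasing position")
    rate = df.iloc[:, 1].astype(float).to_numpy()
    if df.shape[1] >= 3:
        cm = df.iloc[:, 2].astype(float).to_numpy()
        if np.any(np.diff(cm) < 0):
            raise ValueError("cumulative cM decreases")
    else:
        cm = np.concatenate([[0.0], np.cumsum(np.diff(pos) * rate[:-1] / 1e6)])
    return GeneticMap(
        positions=pos.astype(np.int64), cm=cm, chrom=chrom or "1"
    )


def write_genetic_map(gmap: GeneticMap, path) -> None:
    pos = gmap.positions
    rate = np.zeros(pos.size)
    rate[:-1] = np.diff(gmap.cm) / np.maximum(np.diff(pos), 1) * 1e6
    rate[-1] = rate[-2] if pos.size > 1 else 0.0
    with open(path, "w") as fh:
        fh.write("position COMBINED_rate(cM/Mb) Genetic_Map(cM)\n")
        for p, r, c in zip(pos, rate, gmap.cm):
            fh.write(f"{int(p)} {r:.6f} {c:.6f}\n")


# --------------------------------------------------------------- results

def event_to_dict(ev: AdmixtureEvent) -> dict:
    code = {
        "one date": "1D",
        "one date, multiway": "1MW",
        "multiple dates": "2D",
        "no admixture": "NA",
        "uncertain": "U",
    }[ev.classification]
    return {
        "schema": "haplomix.event/1",
        "classification": ev.classification,
        "result_code": code,
        "dates_generations": [float(d) for d in ev.dates],
        "date_ci": [[float(a), float(b)] for a, b in ev.date_ci],
        "alpha": float(ev.alpha),
        "sources": [
            {
                "alpha": float(s["alpha"]),
                "source1": [float(x) for x in s["source1"]],
                "source2": [float(x) for x in s["source2"]],
            }
            for s in ev.sources
        ],
        "metrics": {k: float(v) for k, v in ev.metrics.items()},
        "p_value": float(ev.p_value),
        "bootstrap_dates": [float(d) for d in ev.bootstrap_dates],
        "surrogates": [str(s) for s in ev.surrogates],
        "standardised": bool(ev.standardised),
        "notes": list(ev.notes),
    }


def event_from_dict(d: dict) -> AdmixtureEvent:
    return AdmixtureEvent(
        classification=d["classification"],
        dates=list(d["dates_generations"]),
        date_ci=[tuple(ci) for ci in d["date_ci"]],
        alpha=d["alpha"],
        sources=[
            {
                "alpha": s["alpha"],
                "source1": np.array(s["source1"]),
                "source2": np.array(s["source2"]),
            }
            for s in d["sources"]
        ],
        metrics=dict(d["metrics"]),
        p_value=d["p_value"],
        bootstrap_dates=list(d["bootstrap_dates"]),
        surrogates=list(d["surrogates"]),
        standardised=d.get("standardised", False),
        notes=list(d.get("notes", [])),
    )


def write_results(
    objects: dict,
    out_dir,
    config: dict | None = None,
    seed: int | None = None,
    scale_tvd_1000: bool = False,
) -> list[Path]:
    """Write result objects plus a run manifest.

    ``objects`` maps a name to one of: a pandas DataFrame (written as
    TSV), an AdmixtureEvent (JSON), a square matrix given as
    ``(matrix, labels)`` (TSV with a header row of labels; TVD matrices
    optionally scaled by 1000), or any JSON-serialisable object.
    The output directory is checked for writability before anything is
    computed or written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("")
    except OSError as e:
        raise OSError(f"output directory {out} is not writable: {e}") from e
    probe.unlink()

    written = []
    for name, obj in objects.items():
        if isinstance(obj, pd.DataFrame):
            p = out / f"{name}.tsv"
            obj.to_csv(p, sep="\t", index=False, float_format="%.6g")
        elif isinstance(obj, AdmixtureEvent):
            p = out / f"{name}.json"
            p.write_text(json.dumps(event_to_dict(obj), indent=1))
        elif (
            isinstance(obj, tuple) and len(obj) == 2
            and isinstance(obj[0], np.ndarray)
        ):
            mat, labels = obj
            if scale_tvd_1000 and name.lower().startswith("tvd"):
                mat = mat * 1000.0
            p = out / f"{name}.tsv"
            pd.DataFrame(mat, index=labels, columns=labels).to_csv(
                p, sep="\t", float_format="%.6g"
            )
        else:
            p = out / f"{name}.json"
            p.write_text(json.dumps(obj, indent=1, default=_json_default))
        written.append(p)
    manifest = {
        "schema": "haplomix.manifest/1",
        "version": __version__,
        "seed": seed,
        "config": config or {},
        "outputs": [p.name for p in written],
        "tvd_scaled_by_1000": scale_tvd_1000,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    written.append(mpath)
    return written


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if is_dataclass(o):
        return asdict(o)
    raise TypeError(f"cannot serialise {type(o)}")
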