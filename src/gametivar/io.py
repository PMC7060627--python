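"""Parameter file, input readers, output writers, and the run pipeline.

Input formats
-------------
parameter file
    ``key = value`` lines, ``#`` comments. Required keys: ``genotype_file``,
    ``map_file``, ``effects_file``, ``output_prefix``. Optional keys (with
    defaults): ``genotype_format`` (haps|vcf, haps), ``distance_mode``
    (cM|rate, cM), ``output_variance``/``output_covariance``/``output_ebv``/
    ``output_crv``/``output_hom`` (all on), ``i_f`` (1.5), ``z`` (1.96),
    ``d`` (0.1), ``chromosomes`` (comma list, default all), ``strict``
    (false), ``seed`` (0). Unknown keys are an error.
haplotype table (``haps``)
    whitespace-delimited, two lines per individual per chromosome:
    ``individual_id chromosome hap_label allele allele ...``, alleles 0/1.
map
    TSV ``chromosome  marker_id  value``; value is the cumulative cM
    position (cM mode) or the recombination rate to the next marker (rate
    mode; the last marker's value may be omitted and is ignored).
effects
    TSV with header ``marker_id  <trait> ...``.
phased VCF
    biallelic records with ``|``-phased GT; haplotype allele 1 = REF (the
    package-wide reference-allele convention). Map positions still come
    from the map file — base pairs are never used as genetic distance.

Outputs are up to five TSVs (variance, covariance, ebv, crv, hom), one
header line each, rows in input individual order, written incrementally per
individual so memory scales with markers, not individuals. Floats are
formatted to 6 significant digits. A run manifest (config echo + input
checksums) is written alongside.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (AlignmentError, EffectTable, GameticReport, GeneticMap,
                   HaplotypePair, align_effects_to_map)
from .gametic import individual_report
from .selection import SelectionParams

logger = logging.getLogger("gametivar")

__all__ = [
    "RunConfig",
    "read_config",
    "read_haps",
    "read_phased_vcf",
    "read_map",
    "read_effects",
    "write_haps",
    "write_map",
    "write_effects",
    "write_outputs",
    "run_pipeline",
]

_OUTPUTS = ("variance", "covariance", "ebv", "crv", "hom")


@dataclass
class RunConfig:
    genotype_file: str
    map_file: str
    effects_file: str
    output_prefix: str
    genotype_format: str = "haps"
    distance_mode: str = "cM"
    outputs: dict = field(
        default_factory=lambda: {k: True for k in _OUTPUTS})
    selection: SelectionParams = field(default_factory=SelectionParams)
    chromosomes: list[str] | None = None
    strict: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genotype_format not in ("haps", "vcf"):
            raise ValueError("genotype_format must be one of: haps, vcf")
        if self.distance_mode not in ("cM", "rate"):
            raise ValueError("distance_mode must be one of: cM, rate")
        if not any(self.outputs.values()):
            raise ValueError("at least one output must be enabled")


_BOOL = {"true": True, "on": True, "1": True, "yes": True,
         "false": False, "off": False, "0": False, "no": False}

_REQUIRED = ("genotype_file", "map_file", "effects_file", "output_prefix")
_KNOWN = set(_REQUIRED) | {
    "genotype_format", "distance_mode", "chromosomes", "strict", "seed",
    "i_f", "z", "d",
} | {f"output_{k}" for k in _OUTPUTS}


def _parse_bool(key: str, raw: str) -> bool:
    try:
        return _BOOL[raw.lower()]
    except KeyError:
        raise ValueError(f"{key} must be on/off, got {raw!r}") from None


def read_config(path: str) -> RunConfig:
    """Parse and validate a parameter file; all checks run before any
    computation and a summary is logged."""
    kv: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in _KNOWN:
                raise ValueError(
                    f"{path}:{lineno}: unknown parameter {key!r}")
            if key in kv:
                raise ValueError(f"{path}:{lineno}: duplicate key {key!r}")
            kv[key] = val
    for key in _REQUIRED:
        if key not in kv:
            raise ValueError(f"{path}: missing required parameter {key!r}")

    gf = kv.get("genotype_format", "haps")
    if gf not in ("haps", "vcf"):
        raise ValueError(f"genotype_format must be one of: haps, vcf "
                         f"(got {gf!r})")
    dm = kv.get("distance_mode", "cM")
    if dm not in ("cM", "rate"):
        raise ValueError(f"distance_mode must be one of: cM, rate "
                         f"(got {dm!r})")
    outputs = {k: _parse_bool(f"output_{k}", kv[f"output_{k}"])
               if f"output_{k}" in kv else True for k in _OUTPUTS}
    sel = SelectionParams(
        i_f=float(kv.get("i_f", 1.5)),
        z=float(kv.get("z", 1.96)),
        d=float(kv.get("d", 0.1)),
    )
    chroms = None
    if "chromosomes" in kv and kv["chromosomes"].lower() != "all":
        chroms = [c.strip() for c in kv["chromosomes"].split(",") if c.strip()]
    cfg = RunConfig(
        genotype_file=kv["genotype_file"],
        map_file=kv["map_file"],
        effects_file=kv["effects_file"],
        output_prefix=kv["output_prefix"],
        genotype_format=gf,
        distance_mode=dm,
        outputs=outputs,
        selection=sel,
        chromosomes=chroms,
        strict=_parse_bool("strict", kv.get("strict", "false")),
        seed=int(kv.get("seed", 0)),
    )
    for key in ("genotype_file", "map_file", "effects_file"):
        p = getattr(cfg, key)
        if not os.path.isfile(p):
            raise ValueError(f"{key} does not exist: {p}")
    logger.info("config: %d input files, format=%s, mode=%s, outputs=%s",
                3, cfg.genotype_format, cfg.distance_mode,
                [k for k, v in cfg.outputs.items() if v])
    return cfg


def read_map(path: str, mode: str) -> dict[str, GeneticMap]:
    """Read a map file into per-chromosome GeneticMaps (file order kept)."""
    if mode not in ("cM", "rate"):
        raise ValueError("mode must be 'cM' or 'rate'")
    chrom_ids: dict[str, list[str]] = {}
    chrom_vals: dict[str, list[float | None]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected "
                                 "'chromosome marker_id value'")
            chrom, mid = parts[0].strip(), parts[1].strip()
            raw = parts[2].strip() if len(parts) > 2 else ""
            val = float(raw) if raw else None
            ids = chrom_ids.setdefault(chrom, [])
            if mid in ids:
                raise ValueError(
                    f"{path}:{lineno}: duplicated marker_id {mid!r} "
                    f"on chromosome {chrom!r}")
            ids.append(mid)
            chrom_vals.setdefault(chrom, []).append(val)
    maps: dict[str, GeneticMap] = {}
    for chrom, ids in chrom_ids.items():
        vals = chrom_vals[chrom]
        if mode == "cM":
            if any(v is None for v in vals):
                raise ValueError(
                    f"{path}: missing cM position on chromosome {chrom!r}")
            maps[chrom] = GeneticMap(chrom, ids,
                                     positions_cM=np.asarray(vals, float))
        else:
            rates = vals[:-1] if len(vals) > 1 else []
            if any(v is None for v in rates):
                raise ValueError(
                    f"{path}: missing adjacent rate on chromosome {chrom!r}")
            maps[chrom] = GeneticMap(chrom, ids,
                                     adjacent_rates=np.asarray(rates, float))
    return maps


def read_effects(path: str) -> EffectTable:
    """Read a marker-by-trait effect TSV (header: marker_id, traits...)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t") if "\t" in header else header.split()
        if len(cols) < 2 or cols[0] != "marker_id":
            raise ValueError(
                f"{path}: header must be 'marker_id <trait> ...'")
        traits = cols[1:]
        ids, rows = [], []
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != len(cols):
                raise ValueError(f"{path}:{lineno}: expected "
                                 f"{len(cols)} columns")
            ids.append(parts[0].strip())
            rows.append([float(x) for x in parts[1:]])
    return EffectTable(ids, traits, np.asarray(rows, float))


def read_haps(path: str, maps: dict[str, GeneticMap]
              ) -> dict[str, dict[str, HaplotypePair]]:
    """Read the two-line-per-individual haplotype table.

    Returns individual_id -> chromosome -> HaplotypePair, in file order
    (deterministic)."""
    pending: dict[tuple[str, str], list[np.ndarray]] = {}
    out: dict[str, dict[str, HaplotypePair]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 'individual chromosome "
                    "hap_label allele ...'")
            iid, chrom = parts[0], parts[1]
            alleles = parts[3:]
            bad = [a for a in alleles if a not in ("0", "1")]
            if bad:
                raise ValueError(
                    f"{path}:{lineno}: allele {bad[0]!r} is not 0/1")
            if chrom not in maps:
                raise ValueError(
                    f"{path}:{lineno}: chromosome {chrom!r} absent from map")
            if len(alleles) != maps[chrom].n_markers:
                raise ValueError(
                    f"{path}:{lineno}: {len(alleles)} alleles but map has "
                    f"{maps[chrom].n_markers} markers on {chrom!r}")
            hap = np.array(alleles, dtype=np.int8)
            key = (iid, chrom)
            pending.setdefault(key, []).append(hap)
            if len(pending[key]) == 2:
                a, b = pending.pop(key)
                out.setdefault(iid, {})[chrom] = HaplotypePair(iid, chrom, a, b)
            elif len(pending[key]) > 2:
                raise ValueError(
                    f"{path}:{lineno}: more than two haplotype lines for "
                    f"{iid!r} on {chrom!r}")
    if pending:
        (iid, chrom) = next(iter(pending))
        raise ValueError(
            f"{path}: odd number of haplotype lines for {iid!r} on {chrom!r}")
    return out


def read_phased_vcf(
    path: str,
    chromosomes: list[str] | None = None,
    strict: bool = False,
) -> tuple[dict[str, list[str]], dict[str, dict[str, HaplotypePair]]]:
    """Read phased haplotypes from a VCF.

    Haplotype allele 1 means the REF allele (package-wide convention).
    Multi-allelic, unphased or part-missing records are an error under
    ``strict`` and are dropped (for all individuals, with a logged count)
    otherwise. Returns (chromosome -> marker id list, individual ->
    chromosome -> HaplotypePair); genetic positions must come from the map
    file — the VCF supplies only bp.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    markers: dict[str, list[str]] = {}
    hapdata: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    dropped = 0
    for rec in vcf:
        chrom = rec.CHROM
        if chromosomes is not None and chrom not in chromosomes:
            continue
        mid = rec.ID if rec.ID not in (None, ".") else f"{chrom}:{rec.POS}"
        if len(rec.ALT) != 1:
            if strict:
                raise ValueError(f"multi-allelic record {mid} in strict mode")
            dropped += 1
            continue
        g = np.asarray(rec.genotypes, dtype=int)  # n_samples x 3 (a, b, phased)
        if np.any(g[:, 0] < 0) or np.any(g[:, 1] < 0) or not np.all(g[:, 2]):
            if strict:
                raise ValueError(
                    f"unphased or missing genotype at record {mid} "
                    "in strict mode")
            dropped += 1
            continue
        markers.setdefault(chrom, []).append(mid)
        # VCF allele 0 is REF; flip so 1 = REF per package convention
        hapdata.setdefault(chrom, []).append(
            (1 - g[:, 0], 1 - g[:, 1]))
    if dropped:
        logger.warning("dropped %d VCF record(s) (multi-allelic, unphased "
                       "or missing)", dropped)
    pairs: dict[str, dict[str, HaplotypePair]] = {s: {} for s in samples}
    for chrom, rows in hapdata.items():
        a = np.stack([r[0] for r in rows], axis=1)  # n_samples x n_markers
        b = np.stack([r[1] for r in rows], axis=1)
        for si, s in enumerate(samples):
            pairs[s][chrom] = HaplotypePair(s, chrom, a[si], b[si])
    return markers, pairs


def write_map(path: str, maps: dict[str, GeneticMap]) -> None:
    with open(path, "w") as fh:
        for gmap in maps.values():
            if gmap.distance_mode == "cM":
                for mid, pos in zip(gmap.marker_ids, gmap.positions_cM):
                    fh.write(f"{gmap.chromosome}\t{mid}\t{pos:.10g}\n")
            else:
                for i, mid in enumerate(gmap.marker_ids):
                    if i < gmap.n_markers - 1:
                        fh.write(f"{gmap.chromosome}\t{mid}\t"
                                 f"{gmap.adjacent_rates[i]:.10g}\n")
                    else:
                        fh.write(f"{gmap.chromosome}\t{mid}\t\n")


def write_effects(path: str, effects: EffectTable) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\t" + "\t".join(effects.trait_names) + "\n")
        for mid, row in zip(effects.marker_ids, effects.effects):
            fh.write(mid + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def write_haps(path: str, individuals: dict[str, dict[str, HaplotypePair]]
               ) -> None:
    with open(path, "w") as fh:
        for iid, by_chrom in individuals.items():
            for chrom, pair in by_chrom.items():
                for label, hap in (("A", pair.hap_a), ("B", pair.hap_b)):
                    fh.write(f"{iid} {chrom} {label} "
                             + " ".join(str(int(x)) for x in hap) + "\n")


def _fmt(x: float) -> str:
    return f"{x:.6g}"


class _OutputWriter:
    """Streams the five report TSVs, one row batch per individual."""

    def __init__(self, config: RunConfig, chromosomes: list[str],
                 trait_names: list[str]):
        self.chroms = chromosomes
        self.files = {}
        chrom_cols = "\t".join(f"chrom_{c}" for c in chromosomes)
        headers = {
            "variance": f"individual\ttrait\t{chrom_cols}\ttotal",
            "covariance": f"individual\ttrait_pair\t{chrom_cols}\ttotal",
            "ebv": f"individual\ttrait\t{chrom_cols}\ttotal",
            "hom": f"individual\ttrait\t{chrom_cols}\ttotal",
            "crv": ("individual\ttrait\tcrv\trpta\tprogeny_n\tprogeny_n_raw\t"
                    + "\t".join(f"crv_ext_chrom_{c}" for c in chromosomes)),
        }
        for kind in _OUTPUTS:
            if config.outputs.get(kind):
                path = f"{config.output_prefix}.{kind}.tsv"
                fh = open(path, "w")
                fh.write(headers[kind] + "\n")
                self.files[kind] = fh

    def write(self, rep: GameticReport) -> None:
        for kind, per, tot in (
            ("variance", rep.variance, rep.variance_total),
            ("ebv", rep.gebv, rep.gebv_total),
            ("hom", rep.hom, rep.hom_total),
        ):
            if kind in self.files:
                for t in rep.trait_names:
                    row = [rep.individual_id, t]
                    row += [_fmt(per[t][c]) for c in self.chroms]
                    row.append(_fmt(tot[t]))
                    self.files[kind].write("\t".join(row) + "\n")
        if "covariance" in self.files:
            for pk in rep.covariance:
                row = [rep.individual_id, f"{pk[0]}:{pk[1]}"]
                row += [_fmt(rep.covariance[pk][c]) for c in self.chroms]
                row.append(_fmt(rep.covariance_total[pk]))
                self.files["covariance"].write("\t".join(row) + "\n")
        if "crv" in self.files:
            for t in rep.trait_names:
                row = [rep.individual_id, t, _fmt(rep.crv[t]),
                       _fmt(rep.rpta[t]), str(rep.progeny_n[t]),
                       _fmt(rep.progeny_n_raw[t])]
                row += [_fmt(rep.crv_by_chrom[t][c]) for c in self.chroms]
                self.files["crv"].write("\t".join(row) + "\n")

    def close(self) -> None:
        for fh in self.files.values():
            fh.close()


def write_outputs(reports, config: RunConfig) -> list[str]:
    """Write the enabled output TSVs for an iterable of reports (streaming)."""
    writer = None
    written: list[str] = []
    try:
        for rep in reports:
            if writer is None:
                writer = _OutputWriter(config, rep.chromosomes,
                                       rep.trait_names)
                written = [fh.name for fh in writer.files.values()]
            writer.write(rep)
    finally:
        if writer is not None:
            writer.close()
    if writer is None:
        raise ValueError("no reports to write")
    return written


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(config: RunConfig) -> None:
    with open(f"{config.output_prefix}.manifest.txt", "w") as fh:
        fh.write("# gametivar run manifest\n")
        for key in ("genotype_file", "map_file", "effects_file"):
            p = getattr(config, key)
            fh.write(f"{key} = {p}  sha256:{_checksum(p)}\n")
        fh.write(f"genotype_format = {config.genotype_format}\n")
        fh.write(f"distance_mode = {config.distance_mode}\n")
        fh.write(f"i_f = {config.selection.i_f}\n")
        fh.write(f"z = {config.selection.z}\n")
        fh.write(f"d = {config.selection.d}\n")
        fh.write(f"strict = {config.strict}\n")


def _load_inputs(config: RunConfig):
    """Read and align all inputs; returns (individuals, maps,
    effects_by_chrom)."""
    maps = read_map(config.map_file, config.distance_mode)
    if config.chromosomes is not None:
        missing = [c for c in config.chromosomes if c not in maps]
        if missing:
            raise ValueError(f"chromosome filter names unknown "
                             f"chromosome(s): {missing}")
        maps = {c: maps[c] for c in config.chromosomes}
    effects = read_effects(config.effects_file)

    if config.genotype_format == "haps":
        individuals = read_haps(config.genotype_file, maps)
    else:
        markers, individuals = read_phased_vcf(
            config.genotype_file, chromosomes=list(maps), strict=config.strict)
        # the VCF defines which loci survived; subset each map accordingly
        for chrom in list(maps):
            keep_ids = set(markers.get(chrom, []))
            idx = [i for i, m in enumerate(maps[chrom].marker_ids)
                   if m in keep_ids]
            if len(idx) != len(keep_ids):
                unknown = keep_ids - set(maps[chrom].marker_ids)
                raise ValueError(
                    f"VCF marker(s) absent from map on {chrom!r}: "
                    f"{sorted(unknown)[:3]}")
            if len(idx) != maps[chrom].n_markers:
                maps[chrom] = maps[chrom].subset(idx)

    effects_by_chrom: dict[str, EffectTable] = {}
    for chrom, gmap in list(maps.items()):
        try:
            aligned = align_effects_to_map(effects, gmap,
                                           strict=config.strict)
        except AlignmentError:
            raise
        if aligned.marker_ids != gmap.marker_ids:
            # lenient drop: restrict map and haplotypes to surviving markers
            keep = [i for i, m in enumerate(gmap.marker_ids)
                    if m in set(aligned.marker_ids)]
            maps[chrom] = gmap.subset(keep)
            for by_chrom in individuals.values():
                if chrom in by_chrom:
                    by_chrom[chrom] = by_chrom[chrom].subset(keep)
        effects_by_chrom[chrom] = aligned
    return individuals, maps, effects_by_chrom


def _one_report(by_chrom, maps, effects_by_chrom, selection):
    chroms = [c for c in maps if c in by_chrom]
    return individual_report(
        {c: by_chrom[c] for c in chroms},
        maps,
        effects_by_chrom,
        params=selection,
    )


def run_pipeline(config: RunConfig, jobs: int = 1) -> list[str]:
    """Full run: read inputs, compute every individual's report, stream the
    outputs. With ``jobs > 1`` individuals are computed in parallel and
    merged in input order, so outputs are byte-identical to a serial run."""
    individuals, maps, effects_by_chrom = _load_inputs(config)
    if not individuals:
        raise ValueError("no individuals found in the genotype file")
    _write_manifest(config)

    if jobs > 1:
        from joblib import Parallel, delayed

        reports = Parallel(n_jobs=jobs)(
            delayed(_one_report)(by_chrom, maps, effects_by_chrom,
                                 config.selection)
            for by_chrom in individuals.values())
        return write_outputs(reports, config)

    def gen():
        for by_chrom in individuals.values():
            yield _one_report(by_chrom, maps, effects_by_chrom,
                              config.selection)

    return write_outputs(gen(), config)
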