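"""End-to-end orchestration: screen → classify → quantify → concordance.

The workflow mirrors how a control laboratory authenticates a declared
single-ingredient herb:

1. **DNA accounting screen** — every sample's ddPCR ingredient assay is
   compared against the copy number expected from its fluorometric DNA
   mass; a measurement below the expected range means part of the DNA is
   not the declared species.
2. **Metabarcoding classification** — the read table is restricted to
   Plantae, converted to read percentages and classified; adulterants
   with any reads, and contaminants with elevated reads, are marked for
   ddPCR confirmation.
3. **Conditional quantification** — for flagged taxa with an available
   species assay and droplet data, the ploidy/target-corrected copy
   percentage (and DNA-mass percentage) is computed against the
   ingredient assay; flagged taxa without an assay are recorded as
   "no assay available".
4. **Concordance** — read% vs copy% pairs are pooled per species into
   correlation/regression summaries and a log-log scatter export.

A manifest (config hash, input hashes, seed, thresholds, version) makes
runs reproducible; given identical config and seed the result bundle is
byte-identical.

`simulate_cohort` builds a complete synthetic input bundle (droplet
amplitude CSV, well map, fluorometry replicates, biased read tables)
from per-sample mass compositions, and `make_demo` writes a ready-to-run
demo emulating a multi-species quality-control blend alongside its
packaged read-count fixture.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accounting import SpeciesAssay, account, expected_range, load_assays
from .adulterant import copy_fraction, mass_fraction
from .concordance import (ConcordancePoint, concordance_stats, reporting_bias,
                          scatter_export)
from .droplets import CallOptions, call_droplets, read_amplitude_csv, write_amplitude_csv
from .poisson import DEFAULT_DROPLET_VOLUME_NL, estimate_lambda, pool_wells
from .reads import (ClassifiedReads, classify, default_class_map, filter_kingdom,
                    load_class_map, read_percentages, read_table_tsv,
                    write_read_tables_tsv)
from .synthetic import (DropletSimParams, MixtureSpec, ReadSimParams,
                        neighbour_misattribution, simulate_droplets,
                        simulate_fluorometry, simulate_mixture_copies,
                        simulate_read_table)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "simulate_cohort",
           "make_demo", "load_config"]

logger = logging.getLogger(__name__)

_PCT_COLUMNS = ("read_pct", "copy_pct", "mass_pct")

#: Read-table distortions used by the default synthetic cohort: severe
#: over-reporting of bindweed, under-reporting of the woody-leaved
#: adulterants, total extraction dropout of sumac, and read leakage from
#: oregano to its close relatives within the mint tribe.
DEFAULT_READ_BIAS = {
    "Convolvulus arvensis": 25.0,
    "Olea europaea": 0.3,
    "Myrtus communis": 0.1,
    "Cistus incanus": 0.5,
}
DEFAULT_DROPOUT = {"Rhus coriaria": 1.0}
DEFAULT_NEIGHBOURS = {
    "Origanum vulgare": ["Thymus spp.", "Mentha x piperita", "Salvia/perilla spp."],
    "Origanum onites": ["Origanum spp."],
}
DEFAULT_LEAK = 0.04


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run (YAML-serialisable)."""

    droplets_csv: str
    wells_tsv: str
    fluorometry_csv: str
    reads_tsv: str
    assays_tsv: str
    outdir: str
    class_map_tsv: str | None = None  # None -> packaged default map
    ingredient_species: str = "Origanum vulgare"
    template_volume_ul: float = 1.8
    read_pct_threshold: float = 5.0
    accounting_k: float = 2.0
    min_droplets: int = 100
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.read_pct_threshold, self.accounting_k) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.template_volume_ul <= 0 or self.droplet_volume_nl <= 0:
            raise ValueError("volumes must be positive")


@dataclass
class PipelineResult:
    outdir: Path
    per_well_calls: pd.DataFrame
    copy_estimates: pd.DataFrame
    accounting: pd.DataFrame
    classified_reads: pd.DataFrame
    quantification: pd.DataFrame
    concordance: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = Path(path).parent
    for key in ("droplets_csv", "wells_tsv", "fluorometry_csv", "reads_tsv",
                "assays_tsv", "class_map_tsv", "outdir"):
        if raw.get(key):
            raw[key] = str((base / raw[key]).resolve()
                           if not Path(raw[key]).is_absolute() else raw[key])
    return RunConfig(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _match_assay(taxon: str, assays: Mapping[str, SpeciesAssay]) -> SpeciesAssay | None:
    """Resolve a reported taxon name to an assay: exact, else unique genus."""
    norm = " ".join(taxon.strip().split()).casefold()
    for name, assay in assays.items():
        if name.casefold() == norm:
            return assay
    genus = norm.split()[0] if norm else ""
    candidates = [a for name, a in assays.items()
                  if name.casefold().split()[0] == genus]
    return candidates[0] if len(candidates) == 1 else None


def _round_pcts(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in _PCT_COLUMNS:
        if col in out.columns:
            out[col] = out[col].round(4)
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full authentication workflow for one input bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assays = load_assays(config.assays_tsv)
    class_map = (load_class_map(config.class_map_tsv)
                 if config.class_map_tsv else default_class_map())
    if config.ingredient_species not in assays:
        raise ValueError(f"no assay for ingredient {config.ingredient_species!r}")

    # --- stage 1: droplet calling and per-well Poisson quantification
    wells = pd.read_csv(config.wells_tsv, sep="\t", comment="#")
    well_map = {(str(r.well), int(r.channel)): (str(r.sample), str(r.species))
                for r in wells.itertuples(index=False)}
    opts = CallOptions(min_droplets=config.min_droplets)
    call_rows, estimates = [], {}
    for ds in read_amplitude_csv(config.droplets_csv):
        key = (ds.well_id, ds.channel)
        if key not in well_map:
            logger.warning("well %s ch%d not in well map; skipped", *key)
            continue
        sample, species = well_map[key]
        call = call_droplets(ds, opts)
        est = estimate_lambda(call, droplet_volume_nl=config.droplet_volume_nl,
                              saturated_ok=True)
        estimates.setdefault((sample, species), []).append(est)
        call_rows.append({
            "well": ds.well_id, "channel": ds.channel, "sample": sample,
            "species": species, "n_total": call.n_total,
            "n_positive": call.n_positive, "n_negative": call.n_negative,
            "threshold": call.threshold,
            "n_rain_reassigned": call.n_rain_reassigned,
            "flags": ";".join(sorted(call.quality_flags)),
            "lambda_hat": est.lambda_hat,
            "copies_per_reaction": est.copies_per_reaction,
        })
    per_well = pd.DataFrame(call_rows)

    pooled = {key: pool_wells(ests) for key, ests in estimates.items()}
    est_rows = [{
        "sample": s, "species": sp, "n_wells": len(estimates[(s, sp)]),
        "n_total": e.n_total, "n_negative": e.n_negative,
        "lambda_hat": e.lambda_hat, "ci_low": e.ci_low, "ci_high": e.ci_high,
        "copies_per_reaction": e.copies_per_reaction,
        "copies_per_ul": e.copies_per_ul, "flags": ";".join(sorted(e.flags)),
    } for (s, sp), e in sorted(pooled.items())]
    copy_est = pd.DataFrame(est_rows)

    # --- stage 2: DNA accounting screen on the declared ingredient
    fluoro = pd.read_csv(config.fluorometry_csv, comment="#")
    acc_rows = []
    ing_assay = assays[config.ingredient_species]
    for sample, group in fluoro.groupby("sample", sort=True):
        key = (str(sample), config.ingredient_species)
        if key not in pooled:
            logger.warning("sample %s: no ingredient ddPCR data; screen skipped",
                           sample)
            continue
        conc = group["conc_ng_ul"].to_numpy(dtype=float)
        mass_mean = float(conc.mean()) * config.template_volume_ul
        mass_sd = (float(conc.std(ddof=1)) * config.template_volume_ul
                   if conc.size > 1 else 0.0)
        rng_ = expected_range(mass_mean, mass_sd, ing_assay, k=config.accounting_k)
        res = account(pooled[key], rng_)
        acc_rows.append({
            "sample": str(sample), "species": config.ingredient_species,
            "template_mass_ng": mass_mean, "template_mass_sd_ng": mass_sd,
            "expected_copies": res.expected_copies,
            "expected_low": res.expected_low, "expected_high": res.expected_high,
            "measured_copies": res.measured_copies, "ratio": res.ratio,
            "flag": res.flag,
        })
    accounting_df = pd.DataFrame(acc_rows)

    # --- stage 3: read classification
    classified: list[ClassifiedReads] = []
    for table in read_table_tsv(config.reads_tsv):
        plant = filter_kingdom(table, "Plantae")
        if plant.total_reads == 0:
            logger.warning("sample %s: empty after Plantae filter", table.sample_id)
            continue
        pct = read_percentages(plant, denominator="retained")
        classified.append(classify(pct, class_map,
                                   threshold_pct=config.read_pct_threshold))
    cls_frames = []
    for c in classified:
        df = c.data.copy()
        df.insert(0, "sample", c.sample_id)
        cls_frames.append(df)
    classified_df = (pd.concat(cls_frames, ignore_index=True)
                     if cls_frames else pd.DataFrame())

    # --- stage 4: conditional ddPCR quantification of flagged taxa
    quant_rows = []
    for c in classified:
        ing_key = (c.sample_id, config.ingredient_species)
        for row in c.data.itertuples(index=False):
            if row.action != "confirm_ddPCR":
                continue
            assay = _match_assay(row.taxon, assays)
            if assay is None:
                logger.warning("sample %s: no assay available for %s",
                               c.sample_id, row.taxon)
                quant_rows.append({"sample": c.sample_id, "taxon": row.taxon,
                                   "species": "", "read_pct": row.read_pct,
                                   "copy_pct": None, "mass_pct": None,
                                   "status": "no assay available"})
                continue
            a_key = (c.sample_id, assay.species)
            if a_key not in pooled or ing_key not in pooled:
                quant_rows.append({"sample": c.sample_id, "taxon": row.taxon,
                                   "species": assay.species,
                                   "read_pct": row.read_pct,
                                   "copy_pct": None, "mass_pct": None,
                                   "status": "no ddPCR data"})
                continue
            cf = copy_fraction(pooled[a_key], pooled[ing_key], assay, ing_assay)
            mp = (mass_fraction(cf, assay, ing_assay)
                  if cf.copy_pct is not None else None)
            quant_rows.append({
                "sample": c.sample_id, "taxon": row.taxon,
                "species": assay.species, "read_pct": row.read_pct,
                "copy_pct": cf.copy_pct, "mass_pct": mp,
                "status": "quantified" if cf.copy_pct is not None
                else ";".join(sorted(cf.flags)),
            })
    quant_df = pd.DataFrame(quant_rows)

    # --- stage 5: concordance between read% and copy%
    conc_rows = []
    points: list[ConcordancePoint] = []
    if not quant_df.empty:
        usable = quant_df[quant_df["copy_pct"].notna()]
        points = [ConcordancePoint(sample_id=r.sample, species=r.species,
                                   read_pct=float(r.read_pct),
                                   copy_pct=float(r.copy_pct))
                  for r in usable.itertuples(index=False)]
        for species in sorted({p.species for p in points}):
            sp_points = [p for p in points if p.species == species]
            if len(sp_points) < 2:
                continue
            st = concordance_stats(sp_points)
            bias = (reporting_bias(sp_points) if len(sp_points) >= 3 else "")
            conc_rows.append({
                "species": species, "n": st.n, "pearson_r": st.pearson_r,
                "slope": st.slope, "intercept": st.intercept,
                "p_value": st.p_value, "reporting_bias": bias,
                "flags": ";".join(sorted(st.flags)),
            })
    conc_df = pd.DataFrame(conc_rows)

    # --- outputs and manifest
    per_well.to_csv(outdir / "per_well_calls.csv", index=False)
    copy_est.to_csv(outdir / "copy_estimates.csv", index=False)
    accounting_df.to_csv(outdir / "accounting.csv", index=False)
    _round_pcts(classified_df).to_csv(outdir / "classified_reads.csv", index=False)
    _round_pcts(quant_df).to_csv(outdir / "quantification.csv", index=False)
    conc_df.to_csv(outdir / "concordance.csv", index=False)
    if points:
        scatter_export(points, outdir / "concordance.png",
                       outdir / "concordance_points.csv")

    cfg_dict = asdict(config)
    manifest = {
        "herbauth_version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "input_sha256": {
            key: _sha256(getattr(config, key))
            for key in ("droplets_csv", "wells_tsv", "fluorometry_csv",
                        "reads_tsv", "assays_tsv")
        },
        "thresholds": {
            "read_pct_threshold": config.read_pct_threshold,
            "accounting_k": config.accounting_k,
            "min_droplets": config.min_droplets,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: thresholds applied %r", manifest["thresholds"])

    return PipelineResult(
        outdir=outdir, per_well_calls=per_well, copy_estimates=copy_est,
        accounting=accounting_df, classified_reads=classified_df,
        quantification=quant_df, concordance=conc_df, manifest=manifest,
    )


def simulate_cohort(
    compositions: Mapping[str, Mapping[str, float]],
    outdir,
    seed: int = 0,
    assays: Mapping[str, SpeciesAssay] | None = None,
    ingredient_species: str = "Origanum vulgare",
    n_droplets: int = 20000,
    template_mass_ng: float = 18.0,
    template_volume_ul: float = 1.8,
    fluorometry_cv: float = 0.05,
    total_reads: int = 10000,
    read_bias: Mapping[str, float] | None = None,
    dropout: Mapping[str, float] | None = None,
    neighbours: Mapping[str, Sequence[str]] | None = None,
    leak: float = DEFAULT_LEAK,
    extra_read_tables=None,
) -> Path:
    """Write a complete synthetic input bundle and return its config path.

    ``compositions`` maps sample name → {species: mass fraction}.  Every
    component species needs assay metadata; each gets one simulated
    ddPCR well per sample.  Read tables are drawn with the default
    distortion regime unless overridden.  Deterministic under ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if assays is None:
        assays = default_assays()
    rng = np.random.default_rng(seed)

    droplet_sets, well_rows, fluoro_rows, read_tables = [], [], [], []
    bias = dict(DEFAULT_READ_BIAS if read_bias is None else read_bias)
    drop = dict(DEFAULT_DROPOUT if dropout is None else dropout)
    nbrs = dict(DEFAULT_NEIGHBOURS if neighbours is None else neighbours)

    well_no = 0
    for sample, comp in compositions.items():
        spec = MixtureSpec(components=tuple(comp.items()),
                           total_template_mass_ng=template_mass_ng)
        true_copies = simulate_mixture_copies(spec, assays)
        for species, copies in true_copies.items():
            well_no += 1
            well_id = f"W{well_no:03d}"
            ds = simulate_droplets(
                DropletSimParams(lambda_true=copies / n_droplets,
                                 n_droplets=n_droplets,
                                 seed=int(rng.integers(0, 2**31 - 1))),
                well_id=well_id,
            )
            droplet_sets.append(ds)
            well_rows.append({"well": well_id, "channel": 1,
                              "sample": sample, "species": species})

        fl = simulate_fluorometry(template_mass_ng / template_volume_ul,
                                  cv=fluorometry_cv,
                                  seed=int(rng.integers(0, 2**31 - 1)))
        for i, rep in enumerate(fl.replicates, start=1):
            fluoro_rows.append({"sample": sample, "replicate": i,
                                "conc_ng_ul": round(rep, 6)})

        # abundance proxy: genome equivalents, the quantity barcoding sees
        ab = {sp: frac / assays[sp].genome_size_1c_pg for sp, frac in comp.items()}
        m = neighbour_misattribution(list(ab), nbrs, leak=leak)
        rt = simulate_read_table(
            ab,
            ReadSimParams(total_reads=total_reads, bias=bias, misattribution=m,
                          dropout=drop, seed=int(rng.integers(0, 2**31 - 1))),
            sample_id=sample,
        )
        read_tables.append(rt)

    if extra_read_tables:
        read_tables.extend(extra_read_tables)

    write_amplitude_csv(droplet_sets, outdir / "droplets.csv")
    pd.DataFrame(well_rows).to_csv(outdir / "wells.tsv", sep="\t", index=False)
    pd.DataFrame(fluoro_rows).to_csv(outdir / "fluorometry.csv", index=False)
    write_read_tables_tsv(read_tables, outdir / "reads.tsv")
    assay_df = pd.DataFrame([asdict(a) for a in assays.values()]).rename(
        columns={"genome_size_1c_pg": "genome_size_1c_pg"})
    assay_df.to_csv(outdir / "assays.tsv", sep="\t", index=False)

    # paths relative to the config file, so the bundle is relocatable
    config = RunConfig(
        droplets_csv="droplets.csv",
        wells_tsv="wells.tsv",
        fluorometry_csv="fluorometry.csv",
        reads_tsv="reads.tsv",
        assays_tsv="assays.tsv",
        outdir="results",
        ingredient_species=ingredient_species,
        template_volume_ul=template_volume_ul,
        seed=seed,
    )
    cfg_path = outdir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return cfg_path


def default_assays() -> dict[str, SpeciesAssay]:
    """The packaged (synthetic, representative) assay metadata table."""
    with resources.files("herbauth.data").joinpath("assays_synthetic.tsv").open() as fh:
        return load_assays(fh)


def esa_composition() -> dict[str, float]:
    """Declared mass fractions of the multi-species quality-control blend."""
    with resources.files("herbauth.data").joinpath("esa_composition.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return dict(zip(df["species"], df["mass_fraction"]))


def make_demo(outdir, seed: int = 0) -> Path:
    """Write a self-contained runnable demo dataset; returns the config path.

    The demo cohort holds four pure oregano samples, three samples
    adulterated with olive leaf at 2/5/10% (m/m), an emulation of the
    multi-species quality-control blend, and — as reads only — the
    packaged quality-control read-count fixture (which includes the
    zero-read sumac row).
    """
    from .reads import esa_read_table

    compositions: dict[str, dict[str, float]] = {
        f"pure_{i}": {"Origanum vulgare": 1.0} for i in range(1, 5)
    }
    for pct in (2, 5, 10):
        compositions[f"olive_{pct}pct"] = {
            "Origanum vulgare": 1.0 - pct / 100.0,
            "Olea europaea": pct / 100.0,
        }
    compositions["esa_like"] = esa_composition()
    return simulate_cohort(compositions, outdir, seed=seed,
                           extra_read_tables=[esa_read_table()])
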