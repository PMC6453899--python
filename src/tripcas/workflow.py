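"""End-to-end orchestration: config, staged execution, caching, fixtures.

The pipeline runs the stages in dependency order — simulate (or load)
reporter libraries and reads, parse/align/call, UID-collapse, profile,
redistribute 1-bp insertion counts under a cleavage model, decompose
effect sizes, and optionally analyze hairpin end-structure reads.  Every
output directory carries a ``manifest.json`` with the config hash, seed
and per-file checksums; a rerun with unchanged inputs reuses cached stage
outputs keyed by those hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .readcall import (
    AlignmentParams,
    GuideTarget,
    MutationCall,
    Indel,
    call_reads,
    collapse_uids,
    deletion_window,
    insertion_window,
)
from .insertion_models import CleavageModel, InsertionCountTable, redistribute_counts
from .profiles import compute_profiles, one_bp_insertion_events
from .effects import fit_effect_model, pairwise_assay_regression
from . import end_structures as es
from . import synthetic

__all__ = [
    "ConfigError",
    "DataError",
    "PipelineConfig",
    "run_pipeline",
    "make_fixtures",
]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "call", "profile", "insmodel", "effects", "ends")


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 at the CLI)."""


class DataError(RuntimeError):
    """Invalid or missing data at run time (exit code 3 at the CLI)."""


@dataclass(frozen=True)
class PipelineConfig:
    """Flat pipeline configuration.

    ``assays`` lists guide/ssODN combinations as ``"<guide>+ssODN"`` /
    ``"<guide>-ssODN"``; guides must exist among the default guide set.
    ``library_path`` optionally loads a previously written library table
    instead of generating one.
    """

    out_dir: str = "tripcas_out"
    seed: int = 0
    n_irs: int = 36
    promoters: str = "PGK"
    assays: str = "sgG1-ssODN,sgG2-ssODN,sgG3-ssODN"
    min_coverage: int = 30
    model: str = "combined"
    barcode_mismatch_tolerance: int = 0
    coverage_mean: float = 60.0
    seq_error_rate: float = 0.001
    microhomology: str = ""
    library_path: str = ""
    with_hcodes: bool = False
    hcodes_n: int = 1000
    hcodes_bisulfite_failure_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ConfigError("min_coverage must be >= 1")
        if self.model not in ("blunt", "staggered", "combined"):
            raise ConfigError(f"unknown model {self.model!r}")
        for spec in self.assay_specs():
            pass  # validates

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = {f.name: f.default for f in dataclasses.fields(cls)}
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, sep, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if not sep or key not in types:
                raise ConfigError(f"unknown config key {key!r}")
            default = defaults[key]
            if isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path) -> None:
        lines = [
            f"{f.name}={getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    def assay_specs(self):
        """[(assay name, GuideTarget, with_ssodn)] from the assays string."""
        guides = {g.name: g for g in synthetic.DEFAULT_GUIDES}
        specs = []
        for token in self.assays.split(","):
            token = token.strip()
            if not token:
                continue
            if token.endswith("+ssODN"):
                name, ss = token[:-6], True
            elif token.endswith("-ssODN"):
                name, ss = token[:-6], False
            else:
                raise ConfigError(f"assay {token!r} must end with +ssODN or -ssODN")
            if name not in guides:
                raise ConfigError(f"unknown guide {name!r} in assay {token!r}")
            specs.append((token, guides[name], ss))
        if not specs:
            raise ConfigError("no assays configured")
        return specs

    def simulation_config(self) -> synthetic.SimulationConfig:
        promoters = tuple((p.strip(), 1.0) for p in self.promoters.split(",") if p.strip())
        micro = None
        if self.microhomology:
            triplet, _, prob = self.microhomology.partition(":")
            micro = (triplet, float(prob))
        return synthetic.SimulationConfig(
            seed=self.seed,
            n_irs=self.n_irs,
            promoters=promoters,
            coverage_mean=self.coverage_mean,
            seq_error_rate=self.seq_error_rate,
            microhomology=micro,
        )

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True) + __version__
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Call serialization (compact bracket syntax)
# ---------------------------------------------------------------------------


def calls_to_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        descriptor = ";".join(
            f"{i.kind}[{i.position}:{i.sequence}]" for i in c.indels
        )
        rows.append(
            {"barcode": c.barcode, "uid": c.uid, "outcome": c.outcome,
             "indels": descriptor, "knockin": int(c.knockin), "score": c.score}
        )
    return pd.DataFrame(
        rows, columns=["barcode", "uid", "outcome", "indels", "knockin", "score"]
    )


def calls_from_frame(df: pd.DataFrame, references: dict) -> list:
    calls = []
    for row in df.itertuples(index=False):
        indels = []
        if isinstance(row.indels, str) and row.indels:
            ref = references[row.barcode]
            for token in row.indels.split(";"):
                kind, rest = token.split("[", 1)
                pos_s, seq = rest.rstrip("]").split(":", 1)
                pos = int(pos_s)
                window = (
                    deletion_window(ref, pos, len(seq))
                    if kind == "del"
                    else insertion_window(ref, pos, seq)
                )
                indels.append(Indel(kind=kind, position=pos, sequence=seq, window=window))
        calls.append(
            MutationCall(
                barcode=row.barcode, uid=row.uid, outcome=row.outcome,
                indels=tuple(indels), knockin=bool(row.knockin), score=float(row.score),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Cache:
    def __init__(self, out: Path, config_hash: str):
        self.out = out
        self.path = out / "manifest.json"
        self.config_hash = config_hash
        self.previous = {}
        if self.path.exists():
            try:
                old = json.loads(self.path.read_text())
                if old.get("config_hash") == config_hash:
                    self.previous = old.get("stages", {})
            except (json.JSONDecodeError, OSError):
                pass
        self.stages: dict = {}
        self.hits: list = []

    def fresh(self, stage: str, outputs: list) -> bool:
        rec = self.previous.get(stage)
        if not rec:
            return False
        for fname, digest in rec.items():
            p = self.out / fname
            if not p.exists() or _sha256(p) != digest:
                return False
        if set(rec) != {str(Path(o).name) for o in outputs}:
            return False
        self.hits.append(stage)
        self.stages[stage] = rec
        return True

    def record(self, stage: str, outputs: list) -> None:
        self.stages[stage] = {Path(o).name: _sha256(Path(o)) for o in outputs}

    def write(self, seed: int) -> None:
        manifest = {
            "config_hash": self.config_hash,
            "seed": seed,
            "version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "cache_hits": self.hits,
            "stages": self.stages,
        }
        self.path.write_text(json.dumps(manifest, indent=2) + "\n")


def _load_library(config: PipelineConfig):
    if config.library_path:
        path = Path(config.library_path)
        if not path.exists():
            raise DataError(f"library file not found: {path}")
        table = pd.read_csv(path, sep="\t")
        return [
            synthetic.ReporterConstruct(
                barcode=r.barcode, promoter=r.promoter,
                promoter_index=r.promoter_index,
                locus=(r.chromosome, int(r.position), r.strand),
                target_region=synthetic.TARGET_REGION,
                propensity=float(r.propensity),
            )
            for r in table.itertuples(index=False)
        ]
    return synthetic.generate_reporter_library(config.simulation_config())


def run_pipeline(config: PipelineConfig, upto: str = "ends") -> dict:
    """Run the staged pipeline into ``config.out_dir``; returns the bundle.

    ``upto`` stops after the named stage.  Stage failures raise
    :class:`DataError`/:class:`ConfigError` naming the stage.
    """
    if upto not in STAGES:
        raise ConfigError(f"unknown stage {upto!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache = _Cache(out, config.hash())
    config.to_file(out / "config.txt")
    bundle: dict = {"out_dir": str(out)}
    last = STAGES.index(upto)
    sim = config.simulation_config()
    specs = config.assay_specs()

    try:
        # -- library + simulate ------------------------------------------
        library = _load_library(config)
        bundle["library"] = library
        lib_path = out / "library.tsv"
        read_paths = {a: out / f"reads_{a}.fastq" for a, _, _ in specs}
        truth_paths = {a: out / f"truth_{a}.tsv" for a, _, _ in specs}
        sim_outputs = [lib_path, *read_paths.values(), *truth_paths.values()]
        if not cache.fresh("simulate", sim_outputs):
            synthetic.library_table(library).to_csv(lib_path, sep="\t", index=False)
            for assay, guide, ss in specs:
                reads, truth = synthetic.simulate_cas9_reads(
                    library, guide, sim, with_ssodn=ss, assay=assay
                )
                synthetic.write_fastq(read_paths[assay], reads)
                truth.to_csv(truth_paths[assay], sep="\t", index=False)
            cache.record("simulate", sim_outputs)
        if last == STAGES.index("simulate"):
            cache.write(config.seed)
            return bundle

        # -- call ---------------------------------------------------------
        refs = {c.barcode: c.target_region for c in library}
        call_paths = {a: out / f"calls_{a}.tsv" for a, _, _ in specs}
        summary_path = out / "call_summary.json"
        call_outputs = [*call_paths.values(), summary_path]
        calls_by_assay: dict = {}
        if cache.fresh("call", call_outputs):
            for assay, _, _ in specs:
                calls_by_assay[assay] = calls_from_frame(
                    pd.read_csv(call_paths[assay], sep="\t", keep_default_na=False), refs
                )
        else:
            summaries = {}
            for assay, guide, ss in specs:
                reads = synthetic.read_fastq(read_paths[assay])
                calls, summary = call_reads(
                    [seq for _, seq in reads], refs, guide,
                    ssodn_insert=synthetic.SSODN_INSERT if ss else None,
                    barcode_mismatch_tolerance=config.barcode_mismatch_tolerance,
                )
                molecules, collapse_stats = collapse_uids(calls)
                calls_by_assay[assay] = molecules
                summaries[assay] = {**summary, "collapse": collapse_stats}
                calls_to_frame(molecules).to_csv(call_paths[assay], sep="\t", index=False)
            summary_path.write_text(json.dumps(summaries, indent=2) + "\n")
            cache.record("call", call_outputs)
        bundle["calls"] = calls_by_assay
        if last == STAGES.index("call"):
            cache.write(config.seed)
            return bundle

        # -- profile ------------------------------------------------------
        prof = compute_profiles(calls_by_assay, min_coverage=config.min_coverage)
        meta = {c.barcode: c.promoter for c in library}
        if not prof.empty:
            prof["promoter"] = prof["barcode"].map(meta)
            assay_meta = {a: (g.name, ss) for a, g, ss in specs}
            prof["guide"] = prof["assay"].map(lambda a: assay_meta[a][0])
            prof["ssodn"] = prof["assay"].map(lambda a: assay_meta[a][1])
        prof_path = out / "profiles.tsv"
        prof.to_csv(prof_path, sep="\t", index=False)
        cache.record("profile", [prof_path])
        bundle["profiles"] = prof
        if last == STAGES.index("profile"):
            cache.write(config.seed)
            return bundle

        # -- insertion models ---------------------------------------------
        model = CleavageModel(kind=config.model)
        redistributed = {}
        ins_paths = []
        for assay, guide, _ in specs:
            frame = guide.frame(synthetic.TARGET_REGION)
            events = one_bp_insertion_events(calls_by_assay[assay], frame)
            table = InsertionCountTable.from_events(
                guide.name, frame.ntref, frame.pam_index, events
            )
            counts, diag = redistribute_counts(table, model)
            redistributed[assay] = (counts, diag)
            p = out / f"insertions_{assay}_{config.model}.tsv"
            counts.to_csv(p, sep="\t")
            ins_paths.append(p)
        cache.record("insmodel", ins_paths)
        bundle["redistributed"] = redistributed
        if last == STAGES.index("insmodel"):
            cache.write(config.seed)
            return bundle

        # -- effects ------------------------------------------------------
        effects_out: dict = {}
        if len(specs) >= 2 and not prof.empty:
            freq = prof.pivot(index="barcode", columns="assay", values="total_mut_freq")
            pairs = {}
            assays = [a for a, _, _ in specs]
            for i in range(len(assays)):
                for j in range(i + 1, len(assays)):
                    a, b = assays[i], assays[j]
                    sub = freq[[a, b]].dropna()
                    if len(sub) >= 3:
                        pairs[f"{a} vs {b}"] = pairwise_assay_regression(sub[a], sub[b])
            effects_out["pairwise"] = pairs
            guides_used = {g.name for _, g, _ in specs}
            complete = (
                not prof.empty
                and prof.groupby("assay")["barcode"].nunique().nunique() == 1
            )
            if len(guides_used) >= 2 and complete:
                fit = fit_effect_model(prof)
                effects_out["eta_squared"] = fit.eta_squared
                effects_out["r_squared"] = fit.r_squared
                effects_out["aliasing"] = fit.aliasing
                fit.anova.to_csv(out / "anova.tsv", sep="\t", index=False)
        eff_path = out / "effects.json"
        eff_path.write_text(json.dumps(effects_out, indent=2, default=float) + "\n")
        cache.record("effects", [eff_path])
        bundle["effects"] = effects_out
        if last == STAGES.index("effects"):
            cache.write(config.seed)
            return bundle

        # -- end structures (optional) ------------------------------------
        if config.with_hcodes:
            import numpy as np

            guide = specs[0][1]
            duplex = synthetic.TARGET_REGION
            frame = guide.frame(duplex)
            catalog = es.enumerate_structures(frame.ntref, frame.pam_index)
            mixture = {
                es.EndStructure(3, 3): 0.6,
                es.EndStructure(3, 4): 0.3,
                es.EndStructure(2, 3): 0.1,
            }
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xE2D5]))
            reads, _ = synthetic.simulate_hcodes_reads(
                frame.ntref, frame.pam_index, mixture, config.hcodes_n,
                bisulfite_failure_rate=config.hcodes_bisulfite_failure_rate, rng=rng,
            )
            reference = es.blunt_reference(frame.ntref, frame.pam_index)
            apex = es.apex_position(frame.ntref, frame.pam_index)
            patterns = []
            for r in reads:
                pat, _reason = es.extract_end_pattern(r, reference, apex)
                if pat is not None:
                    patterns.append(pat)
            ranking = es.match_and_rank(patterns, catalog, masked=True)
            ends_path = out / "end_structures.tsv"
            ranking.to_csv(ends_path, sep="\t", index=False)
            cache.record("ends", [ends_path])
            bundle["end_structures"] = ranking
        cache.write(config.seed)
        return bundle
    except (ConfigError, DataError):
        raise
    except synthetic.GenerationError as exc:
        raise DataError(f"stage failure: {exc}") from exc


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def make_fixtures(seed: int, out_dir) -> dict:
    """Write the bundled small datasets: a 36-IR single-promoter cell-line
    fixture, a multi-promoter pool fixture (seven promoters), and a hairpin
    end-structure fixture.  Regenerates identically from the seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    cell = PipelineConfig(
        out_dir=str(out / "cell_line"), seed=seed, n_irs=36, promoters="PGK",
        assays="sgG1-ssODN,sgG2-ssODN,sgG3-ssODN", coverage_mean=40.0,
        microhomology="CGG:0.4",
    )
    run_pipeline(cell, upto="simulate")
    paths["cell_line"] = cell.out_dir

    pool = PipelineConfig(
        out_dir=str(out / "pool"), seed=seed + 1, n_irs=84,
        promoters="CMV,cMyc,Hoxb1,Nanog,Oct4,p53,PGK",
        assays="sgG2-ssODN,sgG2+ssODN,sgG3-ssODN", coverage_mean=40.0,
    )
    run_pipeline(pool, upto="simulate")
    paths["pool"] = pool.out_dir

    import numpy as np

    guide = synthetic.DEFAULT_GUIDES[1]
    frame = guide.frame(synthetic.TARGET_REGION)
    mixture = {
        es.EndStructure(3, 3): 0.5,
        es.EndStructure(3, 4): 0.3,
        es.EndStructure(2, 3): 0.2,
    }
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1D0]))
    reads, truth = synthetic.simulate_hcodes_reads(
        frame.ntref, frame.pam_index, mixture, 500,
        bisulfite_failure_rate=0.05, rng=rng,
    )
    hdir = out / "hcodes"
    hdir.mkdir(exist_ok=True)
    with open(hdir / "hairpin_reads.fasta", "w") as fh:
        for i, (r, label) in enumerate(zip(reads, truth)):
            fh.write(f">read{i} {label}\n{r}\n")
    paths["hcodes"] = str(hdir)
    return paths
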