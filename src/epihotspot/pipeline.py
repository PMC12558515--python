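"""End-to-end orchestration: sequences -> predictions -> profiles -> hotspots
-> annotation -> differentials -> population burden, with a reproducible
run manifest.

Every intermediate is a file another command can consume; rerunning with an
identical config and seed reproduces byte-identical tabular outputs (the
manifest's timestamp is the only varying field and is excluded from the
config hash).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation import classify_region, diff_hotspots, read_topology, write_diff_tsv
from .binding import BinderThresholds, BindingRecord, SB, classify_binder, parse_netmhc_output
from .errors import EpihotspotError, ValidationError
from .hotspots import (
    annotate_calls,
    build_profile,
    call_hotspots,
    heatmap_matrix,
    write_hotspots_tsv,
)
from .population import read_frequency_table, weighted_hotspot_burden, write_burden_tsv
from .sequences import apply_variants, enumerate_peptides, parse_hgvs_p, read_fasta
from .synthetic import SyntheticPredictor, make_synthetic_allele


@dataclass
class RunConfig:
    """Configuration of an end-to-end run.

    ``predictions`` maps a locus-group label to an engine output file and
    its dialect, e.g. ``{"DRB": {"path": "drb.txt", "dialect":
    "netmhciipan41"}}``; alternatively ``synthetic_alleles > 0`` runs the
    synthetic pseudo-predictor over the antigens.  ``variants`` maps an
    antigen id to HGVS p. labels applied to derive comparator antigens.
    """

    fasta: list[str] = field(default_factory=list)
    variants: dict[str, list[str]] = field(default_factory=dict)
    predictions: dict[str, dict[str, str]] = field(default_factory=dict)
    synthetic_alleles: int = 0
    sb_rank: float = 0.5
    wb_rank: float = 2.0
    min_alleles: int = 1
    k: int = 9
    topology: str | None = None
    frequency_csv: str | None = None
    populations: list[str] = field(default_factory=list)
    out_dir: str = "epihotspot_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config from YAML; keyword overrides win over file values."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for p in list(self.fasta) + [self.topology, self.frequency_csv]:
            if p and not Path(p).exists():
                raise ValidationError(f"configured path does not exist: {p}")
        for locus, source in self.predictions.items():
            if not Path(source["path"]).exists():
                raise ValidationError(
                    f"prediction file for {locus} does not exist: {source['path']}"
                )
        if not self.predictions and self.synthetic_alleles <= 0:
            raise ValidationError(
                "config needs prediction files or synthetic_alleles > 0"
            )
        if not self.fasta:
            raise ValidationError("config needs at least one FASTA path")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with stage context."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, EpihotspotError):
                raise type(exc)(f"[stage {name}] {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest dictionary.

    Outputs per antigen and locus group: a per-start profile TSV, a hotspot
    table TSV (with region labels when a topology map is given), a binary
    heatmap TSV; plus diff TSVs of every derived variant antigen against
    its reference, population burden TSVs, and ``manifest.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = BinderThresholds(sb_rank=config.sb_rank, wb_rank=config.wb_rank)

    with _stage("sequences"):
        antigens = []
        for path in config.fasta:
            antigens.extend(read_fasta(path))
        reference_ids = [a.id for a in antigens]
        by_id = {a.id: a for a in antigens}
        derived: dict[str, str] = {}  # derived id -> reference id
        for antigen_id, labels in config.variants.items():
            if antigen_id not in by_id:
                raise ValidationError(f"variants reference unknown antigen {antigen_id!r}")
            for label in labels:
                variant = parse_hgvs_p(label)
                new_id = f"{antigen_id}__{label}"
                by_id[new_id] = apply_variants(by_id[antigen_id], [variant], new_id=new_id)
                derived[new_id] = antigen_id

    with _stage("predictions"):
        # locus label -> antigen id -> records
        records_by_locus: dict[str, dict[str, list[BindingRecord]]] = {}
        if config.synthetic_alleles > 0:
            panel = [
                make_synthetic_allele(seed=config.seed + i, k=config.k)
                for i in range(config.synthetic_alleles)
            ]
            predictor = SyntheticPredictor(panel, seed=config.seed)
            bucket: dict[str, list[BindingRecord]] = {}
            for antigen_id, seq in by_id.items():
                windows = enumerate_peptides(seq, k=config.k)
                bucket[antigen_id] = predictor.predict(windows)
            records_by_locus["synthetic"] = bucket
        for locus, source in config.predictions.items():
            parsed = parse_netmhc_output(source["path"], source["dialect"])
            bucket = {}
            for r in parsed:
                bucket.setdefault(r.antigen_id, []).append(r)
            records_by_locus[locus] = bucket

    topology_maps = read_topology(config.topology) if config.topology else {}

    manifest_outputs: list[str] = []
    hotspots_by = {}  # (antigen, locus) -> calls
    with _stage("hotspots"):
        for locus, bucket in records_by_locus.items():
            for antigen_id, records in bucket.items():
                seq = by_id.get(antigen_id)
                profile = build_profile(
                    records, thresholds, antigen_length=seq.length if seq else None,
                    k=config.k, panel_id=locus,
                )
                calls = call_hotspots(
                    profile, min_alleles=config.min_alleles, sequence=seq,
                    cores={r.start: r.core for r in records},
                )
                tmap = topology_maps.get(antigen_id) or (
                    topology_maps.get(derived.get(antigen_id, "")) if derived.get(antigen_id) else None
                )
                if tmap is not None:
                    labels = {
                        c.start: classify_region(c.start, tmap, k=config.k) for c in calls
                    }
                    calls = annotate_calls(calls, labels)
                hotspots_by[(antigen_id, locus)] = calls
                stem = f"{_safe(antigen_id)}.{_safe(locus)}"
                profile_path = out / f"{stem}.profile.tsv"
                _write_profile_tsv(profile, profile_path, config)
                hotspot_path = out / f"{stem}.hotspots.tsv"
                write_hotspots_tsv(calls, hotspot_path, locus_group=locus)
                heat = heatmap_matrix(records, thresholds) if records else None
                heat_path = out / f"{stem}.heatmap.tsv"
                if heat is not None:
                    heat.to_csv(heat_path, sep="\t")
                    manifest_outputs.append(str(heat_path))
                manifest_outputs += [str(profile_path), str(hotspot_path)]

    with _stage("diff"):
        for derived_id, ref_id in derived.items():
            for locus in records_by_locus:
                ref_calls = hotspots_by.get((ref_id, locus))
                cmp_calls = hotspots_by.get((derived_id, locus))
                if ref_calls is None or cmp_calls is None:
                    continue
                diff = diff_hotspots(ref_calls, cmp_calls)
                diff_path = out / f"{_safe(derived_id)}.vs.{_safe(ref_id)}.{_safe(locus)}.diff.tsv"
                write_diff_tsv(diff, diff_path)
                manifest_outputs.append(str(diff_path))

    with _stage("population"):
        if config.frequency_csv and config.populations:
            table = read_frequency_table(config.frequency_csv)
            for locus, bucket in records_by_locus.items():
                for antigen_id, records in bucket.items():
                    per_allele: dict[str, set[int]] = {}
                    for r in records:
                        if classify_binder(r, thresholds) == SB:
                            per_allele.setdefault(r.allele.name, set()).add(r.start)
                    for pop in config.populations:
                        burden = weighted_hotspot_burden(per_allele, table, pop)
                        path = out / f"{_safe(antigen_id)}.{_safe(locus)}.{_safe(pop)}.burden.tsv"
                        write_burden_tsv(burden, path)
                        manifest_outputs.append(str(path))

    manifest = {
        "tool": "epihotspot",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "inputs": {
            str(p): _sha256(Path(p))
            for p in list(config.fasta)
            + [s["path"] for s in config.predictions.values()]
            + [p for p in (config.topology, config.frequency_csv) if p]
        },
        "antigens": {"reference": reference_ids, "derived": derived},
        "outputs": sorted(manifest_outputs),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "._-" else "_" for c in name)


def _write_profile_tsv(profile, path: Path, config: RunConfig) -> None:
    with path.open("w") as fh:
        fh.write(
            f"# per-{'start' if profile.mode == 'per_start' else 'residue'} "
            f"strong-binder counts; position is 1-based; seed={config.seed}; "
            f"sb_rank={config.sb_rank}\n"
        )
        fh.write("position\tn_alleles_sb\n")
        for pos, n in profile.as_series().items():
            fh.write(f"{pos}\t{n}\n")
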