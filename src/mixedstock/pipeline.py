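"""End-to-end orchestration: harmonize -> build model variants -> fit -> report.

A single structured config file (YAML) is the source of truth for a run.  Each
requested model variant gets its own subdirectory with four artifacts:
``summary.csv`` (contribution means and 95% credibility intervals),
``convergence.csv`` (per-parameter shrink factors), ``draws.csv`` (thinned
posterior draws in long format) and ``manifest.json`` (inputs, settings,
seeds, exclusions).  A top-level ``run.log`` records rookery exclusions and
orphan decisions; ``provenance.json`` records the resolved configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import hapio
from .model import build_model, fit

logger = logging.getLogger("mixedstock")

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """Validated configuration of one full analysis run."""

    baseline: str
    mixed: str
    outdir: str
    references: str | None = None
    variants: list[int] = field(default_factory=lambda: [1])
    iterations: int = 100_000
    burn_in: int = 50_000
    chains: int = 4
    seed: int = 0
    truncation_window: tuple[int, int] = (0, 490)
    orphan_policy: str = "error"
    c: float = 1.0
    draws_thin: int = 50

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("at least one model variant must be requested")
        bad = [v for v in self.variants if v not in (1, 2, 3, 4)]
        if bad:
            raise ValueError(f"unknown model variants {bad}")
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("iterations must exceed burn_in")
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.orphan_policy not in ("error", "drop"):
            raise ValueError("orphan_policy must be 'error' or 'drop'")
        for path in (self.baseline, self.mixed, self.references):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"input path does not exist: {path}")
        self.truncation_window = tuple(self.truncation_window)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["truncation_window"] = list(self.truncation_window)
        return d


def run(config: RunConfig) -> int:
    """Execute the configured analysis; returns 0 on success, 1 if any variant failed."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    old_level = logger.level
    logger.setLevel(logging.INFO)
    try:
        return _run_inner(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()
        logger.setLevel(old_level)


def _run_inner(config: RunConfig, outdir: Path) -> int:
    baseline = hapio.read_baseline_table(config.baseline)
    mixed = hapio.read_mixed_table(config.mixed)

    classes = None
    if config.references:
        records = hapio.read_fasta(config.references)
        classes = hapio.collapse_to_short_classes(records, window=config.truncation_window)
        merged = {k: v for k, v in classes.items() if len(v) > 1}
        if merged:
            logger.info("short-fragment classes merged: %s", merged)
    baseline, mixed = hapio.harmonize(baseline, mixed, classes=classes,
                                      on_orphan=config.orphan_policy)

    (outdir / "provenance.json").write_text(json.dumps(config.to_dict(), indent=1))

    status = 0
    for variant in config.variants:
        vdir = outdir / f"model{variant}"
        vdir.mkdir(exist_ok=True)
        try:
            spec = build_model(baseline, mixed, variant=variant, c=config.c)
            result = fit(spec, baseline, mixed, chains=config.chains,
                         iterations=config.iterations, burn_in=config.burn_in,
                         seed=config.seed)
        except Exception:
            logger.exception("model variant %d failed", variant)
            status = 1
            continue
        summary = result.summary.theta.copy()
        summary.insert(0, "variant", variant)
        summary.to_csv(vdir / "summary.csv", index=False)
        if result.summary.phi is not None:
            result.summary.phi.to_csv(vdir / "summary_phi.csv", index=False)
        result.convergence.write(vdir / "convergence.csv")
        result.draws.to_frame(thin=config.draws_thin).to_csv(vdir / "draws.csv", index=False)
        manifest = dict(result.manifest)
        manifest.update({
            "baseline": str(config.baseline),
            "mixed": str(config.mixed),
            "references": config.references and str(config.references),
            "truncation_window": list(config.truncation_window),
            "orphan_policy": config.orphan_policy,
            "draws_thin": config.draws_thin,
        })
        (vdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        logger.info("variant %d: max shrink factor %.3f (converged=%s)",
                    variant, result.convergence.max_rhat, result.convergence.converged)
    return status
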