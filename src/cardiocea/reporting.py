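"""End-to-end orchestration: config in, decision tables out.

``run_analysis`` drives the whole pipeline from a single configuration:
synthetic baseline generation, optional calibration, the deterministic
analysis (incremental cost/effect of each monotherapy vs no treatment at
several discounting variants; INHB tables for one-, two- and three-drug
strategies against their conventional baselines) and, when iterations are
requested, the probabilistic sensitivity analysis with acceptability
curves. All tabular outputs are comma-separated UTF-8; a MANIFEST records
the seed, package version and parameter digests, and the run log carries
per-stage timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .calibration import calibrate_incidence
from .markov_engine import PatientProfile
from .model import CvdPolicyModel, NO_TREATMENT, default_profiles, default_strategies
from .parameters import load_parameter_set
from .synthetic_data import DEFAULT_CONFIG, GompertzConfig, generate_baseline_rates
from .treatment import Strategy

__all__ = ["RunConfig", "run_analysis"]

logger = logging.getLogger("cardiocea")


@dataclass
class RunConfig:
    out_dir: Path
    params_dir: Optional[Path] = None
    overrides: dict = field(default_factory=dict)
    profiles: Optional[tuple[PatientProfile, ...]] = None
    strategies: Optional[tuple[Strategy, ...]] = None
    seed: int = 0
    n_iter: int = 0
    jitter_sd: float = 0.0
    gompertz: Optional[Mapping[str, GompertzConfig]] = None
    calibration_targets: Optional[Path] = None
    ceac_profile: Optional[PatientProfile] = None

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: Optional[str | Path] = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        profiles = raw.get("profiles")
        if profiles is not None:
            profiles = tuple(
                PatientProfile(sex=p["sex"], start_age=int(p["start_age"]))
                for p in profiles
            )
        strategies = raw.get("strategies")
        if strategies is not None:
            strategies = tuple(Strategy(drugs=tuple(d)) for d in strategies)
        gompertz = raw.get("gompertz")
        if gompertz is not None:
            gompertz = {
                event: GompertzConfig(**params) for event, params in gompertz.items()
            }
        overrides = dict(raw.get("overrides", {}))
        for key in ("discount_rate", "threshold", "stemi_share",
                    "include_hf_angina_efficacy", "population_variant"):
            if key in raw:
                overrides[key] = raw[key]
        return cls(
            out_dir=Path(out_dir or raw.get("out_dir", "cardiocea_out")),
            params_dir=Path(raw["params_dir"]) if raw.get("params_dir") else None,
            overrides=overrides,
            profiles=profiles,
            strategies=strategies,
            seed=int(raw.get("seed", 0)),
            n_iter=int(raw.get("n_iter", 0)),
            jitter_sd=float(raw.get("jitter_sd", 0.0)),
            gompertz=gompertz,
            calibration_targets=(
                Path(raw["calibration_targets"]) if raw.get("calibration_targets") else None
            ),
            ceac_profile=(
                PatientProfile(**raw["ceac_profile"]) if raw.get("ceac_profile") else None
            ),
        )


def _digest(params) -> str:
    payload = json.dumps(
        {name: df.to_csv(index=False) for name, df in params.to_frames().items()},
        sort_keys=True,
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _read_targets(path: Path) -> dict[tuple[str, int], float]:
    import pandas as pd

    df = pd.read_csv(path)
    return {(r.sex, int(r.band)): float(r.target) for r in df.itertuples()}


def run_analysis(config: RunConfig) -> dict[str, Path]:
    """Run the configured pipeline and write the output bundle.

    Returns the mapping of output names to paths. On a stage failure the
    partial outputs are retained and the MANIFEST records the failure
    before the exception is re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    manifest: dict = {"seed": config.seed, "version": __version__, "status": "running"}
    timings: dict[str, float] = {}

    def emit(name: str, df) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        written[name] = path

    try:
        t0 = time.perf_counter()
        rates = generate_baseline_rates(
            seed=config.seed, config=config.gompertz, jitter_sd=config.jitter_sd
        )
        params = load_parameter_set(
            config.params_dir, dict(config.overrides), baseline_rates=rates
        )
        manifest["parameter_digest"] = _digest(params)
        timings["setup"] = time.perf_counter() - t0

        if config.calibration_targets is not None:
            t0 = time.perf_counter()
            targets = _read_targets(config.calibration_targets)
            result = calibrate_incidence(params, targets)
            emit("calibration", result.to_frame())
            params = params.replace(
                baseline_rates=params.baseline_rates.scaled(result.scale_factors)
            )
            manifest["calibration_converged"] = result.converged
            timings["calibration"] = time.perf_counter() - t0

        model = CvdPolicyModel(params, config.profiles, config.strategies)
        t0 = time.perf_counter()
        fitted = model.fit()
        timings["deterministic"] = time.perf_counter() - t0
        emit("strategy_results", fitted.frame())

        monos = [s for s in model.strategies if len(s.drugs) == 1]
        pairs = [s for s in model.strategies if len(s.drugs) == 2]
        triples = [s for s in model.strategies if len(s.drugs) == 3]
        ccb = Strategy(drugs=("ccb",))
        ccb_thia = Strategy(drugs=("ccb", "thiazide"))

        # monotherapy vs no treatment: incremental cost/effect under the
        # base discounting, no discounting, and costs-only discounting
        rows = []
        for profile in model.profiles:
            for s in monos:
                disc = fitted.compare(s, NO_TREATMENT, profile)
                undisc = fitted.compare(s, NO_TREATMENT, profile, discounted=False)
                rows.append(
                    {
                        "sex": profile.sex,
                        "start_age": profile.start_age,
                        "strategy": s.label,
                        "ic_disc": disc.ic,
                        "ie_disc": disc.ie,
                        "ic_undisc": undisc.ic,
                        "ie_undisc": undisc.ie,
                        "ic_disc_ie_undisc_icer": (
                            disc.ic / undisc.ie if undisc.ie != 0 else np.nan
                        ),
                        "icer": disc.icer,
                        "inhb": disc.inhb,
                    }
                )
        import pandas as pd

        emit("incremental_monotherapy", pd.DataFrame(rows))

        for name, strategies, baseline in (
            ("inhb_monotherapy_vs_none", monos, NO_TREATMENT),
            ("inhb_two_drug_vs_ccb", pairs, ccb),
            ("inhb_three_drug_vs_ccb_thiazide", triples, ccb_thia),
        ):
            if not strategies or baseline not in model.strategies:
                continue
            table = fitted.inhb_table(strategies, baseline)
            flat = table.copy()
            flat.columns = [f"{sex}_{age}" for sex, age in table.columns]
            flat = flat.round(10)
            printed = flat.round(2)
            printed.insert(0, "strategy", printed.index)
            flat.insert(0, "strategy", flat.index)
            emit(name, flat.reset_index(drop=True))
            emit(name + "_2dp", printed.reset_index(drop=True))

        if config.n_iter > 0:
            t0 = time.perf_counter()
            ceac_profile = config.ceac_profile or PatientProfile("male", 70)
            for name, strategies, in (
                ("ceac_monotherapy", [NO_TREATMENT] + monos),
                ("ceac_two_drug", [ccb] + pairs),
                ("ceac_three_drug", [ccb_thia] + triples),
            ):
                if len(strategies) < 2 or strategies[0] not in model.strategies:
                    continue
                psa_res = model.fit_psa(
                    n_iter=config.n_iter,
                    seed=config.seed,
                    profiles=[ceac_profile],
                    strategies=strategies,
                )
                emit(name, psa_res.ceac().to_frame())
            timings["psa"] = time.perf_counter() - t0

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = repr(exc)
        raise
    finally:
        manifest["outputs"] = sorted(p.name for p in written.values())
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        log_lines = [f"cardiocea {__version__} seed={config.seed}"]
        log_lines += [f"{stage}: {dt:.2f}s" for stage, dt in timings.items()]
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return written
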