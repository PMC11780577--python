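"""Deterministic synthetic LC-OzNOxESI runs with known regioisomer truth.

The simulator emulates the acquisition scheme of an ozone/nitrogen/oxygen-fed
heated-ESI LC-MS run: full-scan MS1 cycles interleaved with scheduled PRM
MS2 scans of the OzNOx adduct targets.  MS1 scans carry, per species, the
base-adduct precursor, the OzNOx adduct at a configurable fraction of the
precursor (default 0.10, the adduct yield a tuned source achieves), and
classical in-source ozonolysis aldehyde/Criegee peaks.  PRM MS2 scans carry
the class-rule diagnostic ions for every species falling inside the target's
isolation window — which is how coelution scenarios reproduce the MS1-level
ambiguity that mass selection resolves.

Chromatographic profiles are Gaussian in RT.  Noise, when enabled, is
multiplicative log-normal on intensities, Gaussian ppm jitter on m/z, and a
uniform random baseline.  Identical seeds give identical output.

What this emulates and what it does not: peak shapes, adduct yields, class
fragmentation patterns, position-dependent response decline, coelution and
mass degeneracy are represented; isotope envelopes, detector saturation,
real chromatographic tailing and ozonolysis kinetics are not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .lipid_core import ADDUCTS, LipidAnnotation, parse_annotation
from .oznox_chem import (
    CLASS_RULES,
    ClassRule,
    build_prm_targets,
    enumerate_cleavages,
    expected_roles,
    ms2_product,
    oznox_precursor,
    ozesi_products,
    adduct_mz,
)
from .lipid_core import composition
from .spectra_io import Scan, write_mzml, write_peak_tsv

__all__ = [
    "SimulatedSpecies",
    "ScenarioSpec",
    "simulate_run",
    "preset_scenarios",
    "PRESET_NAMES",
    "write_run",
]

BASE_INTENSITY = 1.0e6       # MS1 precursor apex per unit amount
MS2_YIELD = 0.05             # diagnostic-ion apex fraction per unit amount
CRIEGEE_FRACTION = 0.5       # Criegee intensity relative to its aldehyde
GAUSS_FLOOR = 1e-4           # drop peaks below this fraction of apex


@dataclass(frozen=True)
class SimulatedSpecies:
    """One ground-truth species: annotation with complete n-positions."""

    annotation: LipidAnnotation
    amount: float            # relative amount, arbitrary units
    rt_apex: float           # minutes
    rt_sigma: float = 0.05   # minutes

    def __post_init__(self):
        if self.amount <= 0 or self.rt_sigma <= 0:
            raise ValueError("amount and rt_sigma must be positive")
        if not self.annotation.positions_complete:
            raise ValueError(
                f"{self.annotation}: simulator needs complete n-positions"
            )


@dataclass(frozen=True)
class ScenarioSpec:
    """A full simulation scenario."""

    species: tuple[SimulatedSpecies, ...]
    oznox_yield: float = 0.10       # OzNOx adduct / precursor, MS1
    ozesi_yield: float = 0.05       # aldehyde / precursor per cleavage, MS1
    decline: float = 1.0            # per-position response factor^rank
    ppm_sigma: float = 0.0          # Gaussian m/z jitter, ppm
    noise_cv: float = 0.0           # multiplicative log-normal CV
    baseline: float = 0.0           # max intensity of random baseline peaks
    n_baseline_peaks: int = 0
    scan_interval: float = 0.02     # minutes per MS1 cycle
    rt_span: tuple[float, float] = (0.0, 2.0)
    rt_window: float = 0.5          # PRM scheduling half-window, minutes
    isolation_width: float = 1.0    # Th
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        if not 0 < self.oznox_yield <= 1:
            raise ValueError("oznox_yield must be in (0, 1]")
        if not self.species:
            raise ValueError("scenario needs at least one species")


def _gauss(t: float, apex: float, sigma: float) -> float:
    return math.exp(-0.5 * ((t - apex) / sigma) ** 2)


def simulate_run(
    spec: ScenarioSpec,
) -> tuple[list[Scan], pd.DataFrame]:
    """Simulate one LC run; returns (scans, ground-truth ledger).

    The ledger has one row per theoretical peak family (species, ms_level,
    role, cleavage, exact m/z, apex intensity) so every simulated peak above
    baseline maps back to its origin.
    """
    rng = np.random.default_rng(spec.seed)
    ledger_rows: list[dict] = []
    # theoretical peak families per species
    families: list[dict] = []
    for sp in spec.species:
        ann = sp.annotation
        rule = CLASS_RULES[ann.lipid_class]
        neutral = composition(ann)
        # the run is positive-mode; classes whose survey adduct is negative
        # (FA) show their ammoniated species at the MS1 level
        prec_adduct = (
            rule.base_adduct if rule.base_adduct.charge > 0
            else ADDUCTS["[M+NH4]+"]
        )
        prec_mz = adduct_mz(neutral, prec_adduct)
        apex1 = sp.amount * BASE_INTENSITY
        fam = {
            "species": sp, "rule": rule,
            "ms1": [("precursor", None, prec_mz, apex1),
                    ("oznox_precursor", None,
                     oznox_precursor(ann, "+", rule).mz,
                     apex1 * spec.oznox_yield)],
            "ms2": [],
            "oznox_mz": oznox_precursor(ann, "+", rule).mz,
        }
        events = enumerate_cleavages(ann)
        # within-chain rank of p (= u, the count of lower C=C) drives the
        # optional position-dependent response decline
        for prod in ozesi_products(ann, rule):
            ev = prod.cleavage
            factor = spec.decline ** ev.u
            frac = spec.ozesi_yield * factor
            if prod.role == "ozesi_criegee":
                frac *= CRIEGEE_FRACTION
            fam["ms1"].append((prod.role, ev, prod.mz, apex1 * frac))
        for ev in events:
            factor = spec.decline ** ev.u
            for role in expected_roles(rule):
                prod = ms2_product(ann, rule, role, ev.p, ev.u, ev)
                fam["ms2"].append(
                    (role, ev, prod.mz,
                     sp.amount * BASE_INTENSITY * MS2_YIELD * factor)
                )
        families.append(fam)
        for level, entries in (("1", fam["ms1"]), ("2", fam["ms2"])):
            for role, ev, mz, apex in entries:
                ledger_rows.append({
                    "species": str(sp.annotation),
                    "ms_level": int(level),
                    "role": role,
                    "p": ev.p if ev else None,
                    "u": ev.u if ev else None,
                    "mz": mz,
                    "apex_intensity": apex,
                    "rt_apex": sp.rt_apex,
                })
    # PRM targets: unique OzNOx precursor m/z with merged RT windows
    targets: dict[float, list[float]] = {}
    for fam in families:
        mz = round(fam["oznox_mz"], 6)
        sp = fam["species"]
        targets.setdefault(mz, []).extend(
            [sp.rt_apex - spec.rt_window, sp.rt_apex + spec.rt_window]
        )
    target_windows = {
        mz: (min(edges), max(edges)) for mz, edges in targets.items()
    }

    def jitter_mz(mz: float) -> float:
        if spec.ppm_sigma <= 0:
            return mz
        return mz * (1.0 + rng.normal(0.0, spec.ppm_sigma) * 1e-6)

    def jitter_intensity(val: float) -> float:
        if spec.noise_cv <= 0:
            return val
        sigma = math.sqrt(math.log(1.0 + spec.noise_cv ** 2))
        return val * rng.lognormal(-0.5 * sigma**2, sigma)

    scans: list[Scan] = []
    t = spec.rt_span[0]
    while t < spec.rt_span[1] + 1e-12:
        # MS1 full scan
        mzs, its = [], []
        for fam in families:
            sp = fam["species"]
            g = _gauss(t, sp.rt_apex, sp.rt_sigma)
            if g < GAUSS_FLOOR:
                continue
            for role, ev, mz, apex in fam["ms1"]:
                mzs.append(jitter_mz(mz))
                its.append(jitter_intensity(apex * g))
        if spec.n_baseline_peaks and spec.baseline > 0:
            mzs.extend(rng.uniform(100.0, 1100.0, spec.n_baseline_peaks))
            its.extend(rng.uniform(0.0, spec.baseline, spec.n_baseline_peaks))
        scans.append(Scan(1, t, "+", mz=mzs, intensity=its))
        # scheduled PRM MS2 scans
        for j, (tmz, (lo, hi)) in enumerate(sorted(target_windows.items())):
            if not lo <= t < hi:
                continue
            mzs2, its2 = [], []
            for fam in families:
                if abs(fam["oznox_mz"] - tmz) > spec.isolation_width / 2:
                    continue
                sp = fam["species"]
                g = _gauss(t, sp.rt_apex, sp.rt_sigma)
                if g < GAUSS_FLOOR:
                    continue
                for role, ev, mz, apex in fam["ms2"]:
                    mzs2.append(jitter_mz(mz))
                    its2.append(jitter_intensity(apex * g))
            if spec.n_baseline_peaks and spec.baseline > 0:
                nb = spec.n_baseline_peaks
                mzs2 = list(mzs2) + list(rng.uniform(50.0, 900.0, nb))
                its2 = list(its2) + list(
                    rng.uniform(0.0, spec.baseline * MS2_YIELD, nb)
                )
            scans.append(Scan(
                2, t + (j + 1) * spec.scan_interval / (len(target_windows) + 1),
                "+", precursor_mz=tmz,
                isolation_width=spec.isolation_width,
                mz=mzs2, intensity=its2,
            ))
        t += spec.scan_interval
    ledger = pd.DataFrame(ledger_rows)
    return scans, ledger


def write_run(
    spec: ScenarioSpec, out_dir: str | Path, stem: str = "run"
) -> dict[str, Path]:
    """Simulate and write mzML + TSV peak list + ledger TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scans, ledger = simulate_run(spec)
    paths = {
        "mzml": out_dir / f"{stem}.mzML",
        "tsv": out_dir / f"{stem}.peaks.tsv",
        "ledger": out_dir / f"{stem}.ledger.tsv",
    }
    write_mzml(scans, paths["mzml"])
    write_peak_tsv(scans, paths["tsv"])
    ledger.to_csv(paths["ledger"], sep="\t", index=False, float_format="%.6f")
    return paths


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _species(text: str, amount: float, rt: float, sigma: float = 0.05):
    return SimulatedSpecies(parse_annotation(text), amount, rt, sigma)


def preset_scenarios(name: str, seed: int = 0) -> ScenarioSpec:
    """Registered demonstration scenarios.

    * ``pc_22_6`` — a single polyunsaturated PC, the predominant plasma
      docosahexaenoyl species, six C=C;
    * ``pe_pair`` — PE 16:1(n-7)_18:1(n-7): two chains whose C=C share
      (p, u), hence mass-degenerate diagnostic ions;
    * ``fa_16_1_seven_isomers`` — seven coeluting palmitoleate regioisomers
      with the naturally dominant n-7 (92.1 parts), n-9 (6.9) and five
      trace isomers (0.2 each);
    * ``lpc_coelution`` — LPC 22:4(n-6,9,12,15) coeluting with
      LPC 18:1(n-9): the n-15 aldehyde of the former is formula-identical
      to the n-11 aldehyde of an LPC 18:1, confounding MS1-level assignment;
    * ``lpc_18_1_75_25`` — a 75/25 n-9/n-7 LPC 18:1 mixture for partition
      recovery.
    """
    presets = {
        "pc_22_6": lambda: ScenarioSpec(
            (_species("PC 16:0/22:6(n-3,6,9,12,15,18)", 1.0, 1.0),),
            seed=seed,
        ),
        "pe_pair": lambda: ScenarioSpec(
            (_species("PE 16:1(n-7)_18:1(n-7)", 1.0, 1.0),),
            seed=seed,
        ),
        "fa_16_1_seven_isomers": lambda: ScenarioSpec(
            tuple(
                _species(f"FA 16:1(n-{n})", amt, 1.0)
                for n, amt in [(5, 0.2), (6, 0.2), (7, 92.1), (9, 6.9),
                               (10, 0.2), (11, 0.2), (12, 0.2)]
            ),
            seed=seed,
        ),
        "lpc_coelution": lambda: ScenarioSpec(
            (
                _species("LPC 22:4(n-6,9,12,15)", 1.0, 1.00),
                _species("LPC 18:1(n-9)", 1.0, 1.05),
            ),
            seed=seed,
        ),
        "lpc_18_1_75_25": lambda: ScenarioSpec(
            (
                _species("LPC 18:1(n-9)", 75.0, 1.0),
                _species("LPC 18:1(n-7)", 25.0, 1.0),
            ),
            seed=seed,
        ),
    }
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(presets)}"
        )
    return presets[name]()


PRESET_NAMES = (
    "pc_22_6", "pe_pair", "fa_16_1_seven_isomers",
    "lpc_coelution", "lpc_18_1_75_25",
)
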