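"""End-to-end orchestration: simulate -> triangulate -> home ranges ->
distances -> occurrence/threshold -> area comparison -> colocation.

The pipeline is deterministic given (config, seed): every stage draws its
randomness from a child of one SeedSequence, and the report serialises with
sorted keys so identical runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .colocation import FeaturePairSample, PairDistanceModel, dispersion_ratio
from .comparison import BestTModel
from .homerange import build_distance_table, kde_home_range
from .landscape import (
    Extent,
    FeatureSpec,
    LandscapeConfig,
    LocationSet,
    SuppressionFunction,
    generate_features,
    generate_random_points,
    simulate_animal_locations,
    simulate_bearings,
)
from .threshold import AvoidanceThresholdModel, classify_hypotheses
from .triangulation import triangulate

__all__ = ["RunConfig", "run_pipeline", "default_landscape_config"]

ANALYSIS_ROLES = ("homerange_centroid", "homerange_contour", "lek", "nest")


def default_landscape_config(seed: int = 0, n_animals: int = 250, n_random: int = 2000) -> LandscapeConfig:
    """Reference synthetic study area.

    A 5 x 5 km plains landscape with a regular section-line fence grid
    (spacing 1100 m, so the whole area lies within 550 m of a fence) and a
    scatter of wells; animals avoid fences with a hard 500 m threshold.  The
    fence density mirrors surveyed-parcel landscapes where nearly all land is
    within a few hundred meters of a fence, the regime in which the
    cumulative-curve method identifies the threshold.
    """
    extent = Extent(0.0, 0.0, 5000.0, 5000.0)
    return LandscapeConfig(
        extent=extent,
        feature_specs=(
            FeatureSpec(name="fence", kind="grid", spacing_m=1100.0),
            FeatureSpec(name="well", kind="point", count=12),
        ),
        n_animals=n_animals,
        n_random=n_random,
        avoidance_profile={"fence": SuppressionFunction(threshold_m=500.0, form="hard")},
        seed=seed,
    )


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    landscape: LandscapeConfig
    bin_width_m: float = 10.0
    window_m: float = 500.0
    hdi_mass: float = 0.95
    n_draws: int = 10_000
    seed: int = 0
    roles: tuple[str, ...] = ("homerange_centroid",)
    feature_pairs: tuple[tuple[str, str], ...] = ()
    n_fixes_per_animal: int = 0  # >0 exercises the telemetry + home-range stages
    fix_scatter_m: float = 150.0
    use_triangulation: bool = False
    bearing_noise_deg: float = 2.0
    n_leks: int = 0
    n_nests: int = 0
    second_area: LandscapeConfig | None = None  # enables the area comparison

    def __post_init__(self) -> None:
        for v, name in (
            (self.bin_width_m, "bin_width_m"),
            (self.window_m, "window_m"),
            (self.hdi_mass, "hdi_mass"),
            (self.n_draws, "n_draws"),
        ):
            if not v > 0:
                raise ValueError(f"{name} must be positive")
        bad = set(self.roles) - set(ANALYSIS_ROLES)
        if bad:
            raise ValueError(f"unknown analysis role(s): {', '.join(sorted(bad))}")

    def to_jsonable(self) -> dict:
        def landscape_dict(lc):
            return {
                "extent": [lc.extent.xmin, lc.extent.ymin, lc.extent.xmax, lc.extent.ymax],
                "features": [
                    {
                        "name": s.name,
                        "kind": s.kind,
                        "count": s.count,
                        "spacing_m": None if np.isnan(s.spacing_m) else s.spacing_m,
                    }
                    for s in lc.feature_specs
                ],
                "n_animals": lc.n_animals,
                "n_random": lc.n_random,
                "avoidance": {
                    k: {"threshold_m": v.threshold_m, "softness_m": v.softness_m, "form": v.form}
                    for k, v in sorted(lc.avoidance_profile.items())
                },
                "seed": lc.seed,
            }

        doc = {
            "landscape": landscape_dict(self.landscape),
            "bin_width_m": self.bin_width_m,
            "window_m": self.window_m,
            "hdi_mass": self.hdi_mass,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "roles": list(self.roles),
            "feature_pairs": [list(p) for p in self.feature_pairs],
            "n_fixes_per_animal": self.n_fixes_per_animal,
            "fix_scatter_m": self.fix_scatter_m,
            "use_triangulation": self.use_triangulation,
            "bearing_noise_deg": self.bearing_noise_deg,
            "n_leks": self.n_leks,
            "n_nests": self.n_nests,
        }
        if self.second_area is not None:
            doc["second_area"] = landscape_dict(self.second_area)
        return doc


def _simulate_area(lc: LandscapeConfig, rng_seed: int):
    layers = generate_features(lc)
    seeds = np.random.SeedSequence(rng_seed).spawn(3)
    animals = simulate_animal_locations(
        layers, lc.avoidance_profile, lc.n_animals, lc.extent, seed=seeds[0]
    )
    random_pts = generate_random_points(lc.extent, lc.n_random, seed=seeds[1])
    return layers, animals, random_pts


def _simulate_fixes(config: RunConfig, animals: LocationSet, seed) -> dict:
    """Per-animal fix clouds around each centroid, optionally via triangulation."""
    rng = np.random.default_rng(seed)
    fixes = {}
    m = config.n_fixes_per_animal
    for i, (cx, cy) in enumerate(zip(animals.x, animals.y)):
        true_pts = np.column_stack(
            [rng.normal(cx, config.fix_scatter_m, m), rng.normal(cy, config.fix_scatter_m, m)]
        )
        if config.use_triangulation:
            est = np.empty_like(true_pts)
            for j, (px, py) in enumerate(true_pts):
                ang = rng.uniform(0, 2 * np.pi, 3)
                stations = np.column_stack(
                    [px + 800.0 * np.sin(ang), py + 800.0 * np.cos(ang)]
                )
                bearings = simulate_bearings(
                    (px, py),
                    stations,
                    noise_sd_deg=config.bearing_noise_deg,
                    seed=int(rng.integers(2**31 - 1)),
                )
                fix = triangulate(bearings)
                est[j] = fix.location if fix.converged else (px, py)
            fixes[i] = est
        else:
            fixes[i] = true_pts
    return fixes


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Execute every configured stage and return the (JSON-serialisable) report."""
    root = np.random.SeedSequence(config.seed)
    (
        s_area1,
        s_area2,
        s_fixes,
        s_leks,
        s_nests,
        s_models,
        s_coloc,
    ) = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(7)]

    layers, animals, random_pts = _simulate_area(config.landscape, s_area1)
    layer_names = [layer.name for layer in layers]

    location_sets: list[LocationSet] = [random_pts]
    roles = set(config.roles)
    if "homerange_centroid" in roles or "homerange_contour" in roles or config.n_fixes_per_animal:
        location_sets.append(animals)

    home_ranges = []
    contour_set = None
    if config.n_fixes_per_animal >= 5 and "homerange_contour" in roles:
        fixes = _simulate_fixes(config, animals, s_fixes)
        for aid, pts in fixes.items():
            hr = kde_home_range(pts, isopleth=0.95, animal_id=aid)
            if hr is not None:
                home_ranges.append(hr)

    extra_sets = {}
    for role, count, seed in (("lek", config.n_leks, s_leks), ("nest", config.n_nests, s_nests)):
        if role in roles and count > 0:
            extra_sets[role] = simulate_animal_locations(
                layers,
                config.landscape.avoidance_profile,
                count,
                config.landscape.extent,
                seed=seed,
                role=role,
            )
            location_sets.append(extra_sets[role])

    table = build_distance_table(location_sets, layers)

    # per-role x per-feature avoidance thresholds
    model_rng = np.random.default_rng(s_models)
    threshold_records = []
    estimates_by_role: dict[str, dict] = {}
    random_d = {
        name: table[(table["role"] == "random") & (table["feature_class"] == name)][
            "distance_m"
        ].to_numpy()
        for name in layer_names
    }
    for role in config.roles:
        if role == "homerange_centroid":
            role_label = "homerange_centroid"
        elif role == "homerange_contour":
            role_label = None  # handled from contour geometries below
        else:
            role_label = role
        estimates_by_role[role] = {}
        for name, layer in zip(layer_names, layers):
            if role == "homerange_contour":
                if not home_ranges:
                    threshold_records.append(
                        {"role": role, "feature": name, "skipped": "no home ranges (need n_fixes_per_animal >= 5)"}
                    )
                    continue
                from .homerange import nearest_distance

                d_animal = np.array(
                    [nearest_distance(hr.contour, layer) for hr in home_ranges]
                )
            else:
                sel = table[(table["role"] == role_label) & (table["feature_class"] == name)]
                if sel.empty:
                    threshold_records.append(
                        {"role": role, "feature": name, "skipped": "no locations with this role"}
                    )
                    continue
                d_animal = sel["distance_m"].to_numpy()
            if not np.all(np.isfinite(d_animal)) or not np.all(np.isfinite(random_d[name])):
                threshold_records.append(
                    {"role": role, "feature": name, "skipped": "empty feature layer"}
                )
                continue
            model = AvoidanceThresholdModel(
                d_animal, random_d[name], bin_width_m=config.bin_width_m, feature=name
            )
            res = model.fit(
                n_draws=config.n_draws,
                seed=int(model_rng.integers(2**31 - 1)),
                window_m=config.window_m,
                hdi_mass=config.hdi_mass,
            )
            estimates_by_role[role][name] = res.estimate
            rec = res.estimate.to_record()
            rec["role"] = role
            threshold_records.append(rec)

    hypothesis = None
    for role in config.roles:
        if estimates_by_role.get(role):
            hypothesis = classify_hypotheses(estimates_by_role[role])
            hypothesis["role"] = role
            break

    # two-area feature-density comparison (BEST on random-point distances)
    comparison_records = []
    if config.second_area is not None:
        layers2, _, random2 = _simulate_area(config.second_area, s_area2)
        table2 = build_distance_table([random2], layers2)
        common = sorted(set(layer_names) & {l.name for l in layers2})
        for name in common:
            x1 = random_d[name]
            x2 = table2[
                (table2["role"] == "random") & (table2["feature_class"] == name)
            ]["distance_m"].to_numpy()
            if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
                continue
            res = BestTModel(x1, x2).fit(
                n_draws=config.n_draws,
                seed=int(model_rng.integers(2**31 - 1)),
                hdi_mass=config.hdi_mass,
            )
            rec = res.to_record()
            rec["feature"] = name
            comparison_records.append(rec)

    # colocation / dispersion for configured feature pairs (centroids only)
    coloc_rng = np.random.default_rng(s_coloc)
    colocation_records = []
    pairs = config.feature_pairs or tuple(combinations(layer_names, 2))
    if "homerange_centroid" in roles:
        wide = table.pivot_table(
            index=["role", "id"], columns="feature_class", values="distance_m"
        )
        for fa, fb in pairs:
            if fa not in wide.columns or fb not in wide.columns:
                continue
            draws = {}
            ok = True
            for role_label, tag in (("homerange_centroid", "G"), ("random", "R")):
                sub = wide.loc[role_label, [fa, fb]].dropna()
                A = np.maximum(sub[fa].to_numpy(), 1e-6)
                B = np.maximum(sub[fb].to_numpy(), 1e-6)
                if A.size < 10 or not np.all(np.isfinite(A)) or not np.all(np.isfinite(B)):
                    ok = False
                    break
                sample = FeaturePairSample(A=A, B=B, role=role_label, feature_a=fa, feature_b=fb)
                fitted = PairDistanceModel(sample).fit(
                    seed=int(coloc_rng.integers(2**31 - 1))
                )
                draws[tag] = fitted.distance_draws
            if not ok:
                colocation_records.append(
                    {"feature_a": fa, "feature_b": fb, "skipped": "insufficient paired distances"}
                )
                continue
            est = dispersion_ratio(
                draws["G"],
                draws["R"],
                hdi_mass=config.hdi_mass,
                seed=int(coloc_rng.integers(2**31 - 1)),
                feature_a=fa,
                feature_b=fb,
            )
            colocation_records.append(est.to_record())

    config_doc = config.to_jsonable()
    config_hash = hashlib.sha256(
        json.dumps(config_doc, sort_keys=True).encode()
    ).hexdigest()[:16]
    try:
        pkg_version = _pkg_version("featureshy")
    except Exception:  # editable/unbuilt source tree
        pkg_version = "unknown"
    report = {
        "provenance": {
            "config": config_doc,
            "config_hash": config_hash,
            "seed": config.seed,
            "package_version": pkg_version,
        },
        "thresholds": threshold_records,
        "hypothesis": hypothesis,
        "area_comparison": comparison_records,
        "colocation": colocation_records,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for layer in layers:
            fio.write_feature_layer(layer, out / f"features_{layer.name}.geojson")
        fio.write_locations(animals, out / "locations_animals.csv")
        fio.write_locations(random_pts, out / "locations_random.csv")
        table.to_csv(out / "distances.csv", index=False)
        if home_ranges:
            fio.write_home_ranges(home_ranges, out / "home_ranges.geojson")
        pd.DataFrame(
            [r for r in threshold_records if "skipped" not in r]
        ).to_csv(out / "thresholds.csv", index=False)
        if comparison_records:
            pd.DataFrame(comparison_records).to_csv(out / "area_comparison.csv", index=False)
        if colocation_records:
            pd.DataFrame(
                [r for r in colocation_records if "skipped" not in r]
            ).to_csv(out / "colocation.csv", index=False)
        fio.write_report(report, out / "report.json")
    return report
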