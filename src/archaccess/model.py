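"""Model/Results facade over the accessibility pipeline.

`AccessibilityModel` holds the data (a :class:`~archaccess.core.StudyRegion`)
and the analysis settings; :meth:`AccessibilityModel.fit` runs the full
pipeline and returns an :class:`AccessibilityResults` carrying the district
summaries, segment statistics, equity scores and 2SFCA comparator, with a
``summary()`` text table in the reporting convention (km rounded half-up to
2 decimals).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import StudyRegion
from .io import read_region
from .pipeline import PipelineConfig, ResultBundle, report_table, run_pipeline
from .util import round_half_up

__all__ = ["AccessibilityModel", "AccessibilityResults"]


class AccessibilityModel:
    """Healthcare-accessibility analysis of one study region.

    Parameters mirror :class:`~archaccess.pipeline.PipelineConfig`; any
    keyword overrides the default (e.g. ``road_proximity_km=5.0``,
    ``equity_form="ratio"``, ``district_restriction=False``).
    """

    def __init__(self, region: StudyRegion, config: PipelineConfig | None = None, **overrides):
        if config is None:
            config = PipelineConfig(**overrides)
        elif overrides:
            config = PipelineConfig(**{**config.__dict__, **overrides})
        config.validate()
        self.region = region
        self.config = config

    @classmethod
    def from_directory(cls, directory: str | Path, **overrides) -> "AccessibilityModel":
        """Build a model from a GeoJSON/CSV input directory."""
        return cls(read_region(directory), **overrides)

    def fit(self) -> "AccessibilityResults":
        """Run allocation, classification, routing, aggregation, equity
        scoring and the 2SFCA comparator; return the results object."""
        return AccessibilityResults(self, run_pipeline(self.region, self.config))


class AccessibilityResults:
    """Fitted accessibility results for one region."""

    def __init__(self, model: AccessibilityModel, bundle: ResultBundle):
        self.model = model
        self.bundle = bundle

    # -- tidy views ----------------------------------------------------

    @property
    def district_table(self) -> pd.DataFrame:
        """Per-district proportions, route-type means, z, all-routes mean."""
        return self.bundle.district_table

    @property
    def segment_stats(self) -> pd.DataFrame:
        """Per-district descriptive statistics of route segments A–H."""
        return self.bundle.segment_table

    @property
    def routes(self) -> pd.DataFrame:
        return self.bundle.route_table

    @property
    def equity(self) -> pd.DataFrame:
        """Workforce terms (mu, x, y), z, equity value and rank per district."""
        return self.bundle.equity_table

    @property
    def fca(self) -> pd.DataFrame:
        return self.bundle.fca_table

    @property
    def rankings(self) -> list[tuple[int, str]]:
        """(rank, district name) pairs, best equity first."""
        return [(s.rank, s.district_name) for s in self.bundle.equity_scores]

    def save(self, directory: str | Path) -> None:
        self.bundle.write(directory)

    # -- report --------------------------------------------------------

    def summary(self) -> str:
        """Text report: district summary and equity ranking, 2-decimal km."""
        rep = report_table(self.district_table)
        lines = ["Healthcare accessibility summary", "=" * 70]
        for _, row in rep.iterrows():
            lines.append(f"{row['name']} (population {row['population']:,.0f})")
            lines.append(
                f"  reach puskesmas by land: {row['c_pct']:.2f}%   "
                f"hospital by land: {row['e_pct']:.2f}%"
            )

            def cell(v):
                return "-" if pd.isna(v) else f"{v:.2f}"

            lines.append(
                "  mean km (puskesmas land / hospital land / puskesmas naval / "
                "hospital naval): "
                f"{cell(row['mean_puskesmas_land_km'])} / {cell(row['mean_hospital_land_km'])} / "
                f"{cell(row['mean_puskesmas_naval_km'])} / {cell(row['mean_hospital_naval_km'])}"
            )
            lines.append(
                f"  z = {row['z_km']:.2f} km   all-routes mean = "
                f"{row['all_routes_mean_km']:.2f} km"
            )
        if self.bundle.equity_scores:
            lines.append("-" * 70)
            lines.append("Equity ranking (low value = excellent):")
            for s in self.bundle.equity_scores:
                lines.append(
                    f"  {s.rank}. {s.district_name}: equity {round_half_up(s.equity_value, 3):g} "
                    f"(z {round_half_up(s.z, 2):.2f} km, x {round_half_up(s.x, 2):.2f}, "
                    f"y {round_half_up(s.y, 2):.2f} per 1,000)"
                )
        return "\n".join(lines)
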