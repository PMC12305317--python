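"""Reproduction of the published derivable effect sizes from group summaries.

The clinical study this package models reports cohort-level group
summaries (mean +/- sd of dispersions and normalized E-field metrics,
ANOVA F values) together with derived quantities: Cohen's d, effect-size
r, eta-squared, field ratios, percent changes and motor-threshold
percentages.  Every derived quantity that is arithmetic on the printed
summaries is recomputed here through the :mod:`tmsfield.stats` layer and
checked against the printed value at its printed number of decimals.

The group summaries themselves are inputs (printed tables), not outputs:
patient-level E-field values cannot be recomputed without the original
MRIs, so only the derivable arithmetic is an exact reproduction surface.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import (cohens_d_pooled, d_to_r, eta_squared_from_f, GroupSummary,
                    percent_change, percent_mt_from_ratio, ratio)

__all__ = ["PUBLISHED", "reference_table", "reproduce_reference"]

_N = 30  # patients per cohort

#: Published cohort group summaries (label -> GroupSummary) and F statistics.
PUBLISHED = {
    # centroid dispersions (mm), patients
    "disp_functional": GroupSummary("functional dispersion", _N, 13.61, 6.82),
    "disp_anatomical": GroupSummary("anatomical dispersion", _N, 5.17, 2.66),
    "disp_f3": GroupSummary("F3 dispersion", _N, 4.59, 2.75),
    # centroid dispersions (mm), healthy controls
    "hc_disp_functional": GroupSummary("HC functional dispersion", _N, 19.56, 7.03),
    "hc_disp_anatomical": GroupSummary("HC anatomical dispersion", _N, 3.70, 2.54),
    # normalized E_ROI / E_perp at the two targets, LOI-parallel handle
    "par_eroi_functional": GroupSummary("parallel E_ROI functional", _N, 0.68, 0.064),
    "par_eroi_anatomical": GroupSummary("parallel E_ROI anatomical", _N, 0.55, 0.074),
    "par_eperp_functional": GroupSummary("parallel E_perp functional", _N, 0.34, 0.057),
    "par_eperp_anatomical": GroupSummary("parallel E_perp anatomical", _N, 0.27, 0.048),
    # LOI-perpendicular handle
    "perp_eroi_functional": GroupSummary("perpendicular E_ROI functional", _N, 0.66, 0.070),
    "perp_eroi_anatomical": GroupSummary("perpendicular E_ROI anatomical", _N, 0.39, 0.11),
    "perp_eperp_functional": GroupSummary("perpendicular E_perp functional", _N, 0.31, 0.057),
    "perp_eperp_anatomical": GroupSummary("perpendicular E_perp anatomical", _N, 0.18, 0.049),
    # orientation-sweep ratio extrema (E_ROI and E_perp), patients and HCs
    "max_ratio_eroi": GroupSummary("max E_ROI ratio", _N, 2.18, 1.34),
    "min_ratio_eroi": GroupSummary("min E_ROI ratio", _N, 1.23, 0.22),
    "max_ratio_eperp": GroupSummary("max E_perp ratio", _N, 2.52, 1.50),
    "min_ratio_eperp": GroupSummary("min E_perp ratio", _N, 1.11, 0.31),
    "hc_max_ratio_eroi": GroupSummary("HC max E_ROI ratio", _N, 3.27, 2.16),
    "hc_min_ratio_eroi": GroupSummary("HC min E_ROI ratio", _N, 1.41, 0.34),
    "hc_max_ratio_eperp": GroupSummary("HC max E_perp ratio", _N, 3.67, 2.49),
    "hc_min_ratio_eperp": GroupSummary("HC min E_perp ratio", _N, 1.26, 0.46),
}

#: Published one-way ANOVA F statistics (3 groups of 30).
PUBLISHED_F = {
    "spatial_dispersion": 37.60,
    "pair_distance": 72.13,
    "roi_volume": 0.14,
}


def _rows():
    p = PUBLISHED
    d_par = cohens_d_pooled(p["par_eroi_functional"], p["par_eroi_anatomical"])
    d_par_perp_comp = cohens_d_pooled(p["par_eperp_functional"], p["par_eperp_anatomical"])
    d_perp = cohens_d_pooled(p["perp_eroi_functional"], p["perp_eroi_anatomical"])
    d_perp_perp_comp = cohens_d_pooled(p["perp_eperp_functional"], p["perp_eperp_anatomical"])
    d_hc = cohens_d_pooled(p["hc_disp_functional"], p["hc_disp_anatomical"])
    d_max_min = cohens_d_pooled(p["max_ratio_eroi"], p["min_ratio_eroi"])
    d_max_min_perp = cohens_d_pooled(p["max_ratio_eperp"], p["min_ratio_eperp"])
    d_hc_max_min = cohens_d_pooled(p["hc_max_ratio_eroi"], p["hc_min_ratio_eroi"])
    d_hc_max_min_perp = cohens_d_pooled(p["hc_max_ratio_eperp"], p["hc_min_ratio_eperp"])
    r_perp_eroi = ratio(p["perp_eroi_functional"].mean, p["perp_eroi_anatomical"].mean)
    r_par_eroi = ratio(p["par_eroi_functional"].mean, p["par_eroi_anatomical"].mean)

    # (name, provenance, computed value, printed value, printed decimals)
    return [
        ("dispersion_fold_change",
         "functional vs anatomical dispersion, patients",
         ratio(p["disp_functional"].mean, p["disp_anatomical"].mean), 2.63, 2),
        ("f3_vs_functional_reduction_pct",
         "F3 dispersion reduction vs functional",
         -percent_change(p["disp_functional"].mean, p["disp_f3"].mean), 66.27, 2),
        ("f3_vs_anatomical_reduction_pct",
         "F3 dispersion reduction vs anatomical",
         -percent_change(p["disp_anatomical"].mean, p["disp_f3"].mean), 11.2, 1),
        ("eta2_spatial_dispersion",
         "eta^2 from dispersion ANOVA F",
         eta_squared_from_f(PUBLISHED_F["spatial_dispersion"], 3, 3 * _N), 0.46, 2),
        ("eta2_pair_distance",
         "eta^2 from inter-target distance ANOVA F",
         eta_squared_from_f(PUBLISHED_F["pair_distance"], 3, 3 * _N), 0.62, 2),
        ("eta2_roi_volume",
         "eta^2 from ROI volume ANOVA F",
         eta_squared_from_f(PUBLISHED_F["roi_volume"], 3, 3 * _N), 0.003, 3),
        ("cohens_d_parallel_eroi",
         "parallel handle, E_ROI functional vs anatomical", d_par, 1.88, 2),
        ("effect_r_parallel_eroi",
         "r from the parallel E_ROI d", d_to_r(d_par), 0.68, 2),
        ("cohens_d_parallel_eperp",
         "parallel handle, E_perp functional vs anatomical", d_par_perp_comp, 1.33, 2),
        ("effect_r_parallel_eperp",
         "r from the parallel E_perp d", d_to_r(d_par_perp_comp), 0.55, 2),
        ("cohens_d_perpendicular_eroi",
         "perpendicular handle, E_ROI functional vs anatomical", d_perp, 2.93, 2),
        ("effect_r_perpendicular_eroi",
         "r from the perpendicular E_ROI d", d_to_r(d_perp), 0.83, 2),
        ("cohens_d_perpendicular_eperp",
         "perpendicular handle, E_perp functional vs anatomical",
         d_perp_perp_comp, 2.45, 2),
        ("effect_r_perpendicular_eperp",
         "r from the perpendicular E_perp d", d_to_r(d_perp_perp_comp), 0.77, 2),
        ("eroi_ratio_parallel",
         "functional/anatomical E_ROI ratio, parallel handle", r_par_eroi, 1.24, 2),
        ("eroi_ratio_perpendicular",
         "functional/anatomical E_ROI ratio, perpendicular handle",
         r_perp_eroi, 1.69, 2),
        ("eperp_ratio_parallel",
         "functional/anatomical E_perp ratio, parallel handle",
         ratio(p["par_eperp_functional"].mean, p["par_eperp_anatomical"].mean),
         1.26, 2),
        ("eperp_ratio_perpendicular",
         "functional/anatomical E_perp ratio, perpendicular handle",
         ratio(p["perp_eperp_functional"].mean, p["perp_eperp_anatomical"].mean),
         1.72, 2),
        ("functional_drop_pct",
         "functional E_ROI change, parallel -> perpendicular",
         percent_change(p["par_eroi_functional"].mean,
                        p["perp_eroi_functional"].mean), -2.94, 2),
        ("anatomical_drop_pct",
         "anatomical E_ROI change, parallel -> perpendicular",
         percent_change(p["par_eroi_anatomical"].mean,
                        p["perp_eroi_anatomical"].mean), -29.09, 2),
        ("functional_drop_eperp_pct",
         "functional E_perp change, parallel -> perpendicular",
         percent_change(p["par_eperp_functional"].mean,
                        p["perp_eperp_functional"].mean), -8.82, 2),
        ("anatomical_drop_eperp_pct",
         "anatomical E_perp change, parallel -> perpendicular",
         percent_change(p["par_eperp_anatomical"].mean,
                        p["perp_eperp_anatomical"].mean), -33.33, 2),
        # the published %MT values are derived from the ratios at their
        # printed two-decimal precision (100/1.24 and 100/1.69)
        ("percent_mt_parallel",
         "anatomical target %MT at the parallel-handle ratio",
         percent_mt_from_ratio(round(r_par_eroi, 2)), 80.6, 1),
        ("percent_mt_perpendicular",
         "anatomical target %MT at the perpendicular-handle ratio",
         percent_mt_from_ratio(round(r_perp_eroi, 2)), 59.17, 2),
        ("hc_dispersion_cohens_d",
         "HC functional vs anatomical dispersion d", d_hc, 3.00, 2),
        ("hc_dispersion_effect_r",
         "r from the HC dispersion d", d_to_r(d_hc), 0.83, 2),
        ("cohens_d_ratio_extrema_eroi",
         "max vs min E_ROI ratio d, patients", d_max_min, 0.99, 2),
        ("effect_r_ratio_extrema_eroi",
         "r from the E_ROI ratio-extrema d", d_to_r(d_max_min), 0.44, 2),
        ("cohens_d_ratio_extrema_eperp",
         "max vs min E_perp ratio d, patients", d_max_min_perp, 1.30, 2),
        ("effect_r_ratio_extrema_eperp",
         "r from the E_perp ratio-extrema d", d_to_r(d_max_min_perp), 0.55, 2),
        ("hc_cohens_d_ratio_extrema_eroi",
         "max vs min E_ROI ratio d, HCs", d_hc_max_min, 1.20, 2),
        ("hc_effect_r_ratio_extrema_eroi",
         "r from the HC E_ROI ratio-extrema d", d_to_r(d_hc_max_min), 0.52, 2),
        ("hc_cohens_d_ratio_extrema_eperp",
         "max vs min E_perp ratio d, HCs", d_hc_max_min_perp, 1.35, 2),
        ("hc_effect_r_ratio_extrema_eperp",
         "r from the HC E_perp ratio-extrema d", d_to_r(d_hc_max_min_perp), 0.56, 2),
    ]


def reference_table() -> pd.DataFrame:
    """Recompute every derivable published quantity and compare.

    Columns: quantity, provenance, computed, published, decimals, passed.
    ``passed`` holds at the published precision (half a unit in the last
    printed decimal place).
    """
    rows = []
    for name, prov, computed, published, dec in _rows():
        tol = 0.5 * 10.0 ** (-dec) + 1e-12
        rows.append({
            "quantity": name,
            "provenance": prov,
            "computed": computed,
            "published": published,
            "decimals": dec,
            "passed": bool(abs(computed - published) < tol),
        })
    return pd.DataFrame(rows)


def reproduce_reference() -> tuple[pd.DataFrame, bool]:
    """Full derivable-numbers table and whether every row passes."""
    df = reference_table()
    return df, bool(df["passed"].all())
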