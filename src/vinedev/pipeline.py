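"""Glue shared by the analysis drivers, tests and the acceptance script."""

from __future__ import annotations

import pandas as pd

from vinedev.inference_core import blocked_split

__all__ = ["phenology_split", "apex_split", "internode_split"]


def phenology_split(ratings: pd.DataFrame, ratio: float = 0.8, seed: int = 0):
    """80/20 split blocking by year and treatment; a plant-within-year is the
    indivisible unit, so all ratings of one plant in one year stay together."""
    df = ratings.copy()
    df["_unit"] = (df["year"].astype(str) + "/" + df["ring"].astype(str)
                   + "/" + df["plant"].astype(str))
    plan = blocked_split(df, ["year", "trt"], "_unit", ratio, seed)
    mask = plan.mask(df, "_unit")
    return (df[mask].drop(columns="_unit"), df[~mask].drop(columns="_unit"), plan)


def apex_split(apex: pd.DataFrame, ratio: float = 0.8, seed: int = 0):
    """80/20 split blocking by year and treatment with whole shoots as units."""
    df = apex.copy()
    df["_unit"] = (df["year"].astype(str) + "/" + df["ring"].astype(str) + "/"
                   + df["plant"].astype(str) + "/" + df["shoot"].astype(str))
    plan = blocked_split(df, ["year", "trt"], "_unit", ratio, seed)
    mask = plan.mask(df, "_unit")
    return (df[mask].drop(columns="_unit"), df[~mask].drop(columns="_unit"), plan)


def internode_split(internodes: pd.DataFrame, ratio: float = 0.8, seed: int = 0):
    """80/20 split of internode records with whole shoots as units,
    stratified by year, treatment and shoot-size class (terciles of the
    shoot's maximum apex rank) so both partitions see comparable shoots."""
    df = internodes.copy()
    df["_unit"] = (df["year"].astype(str) + "/" + df["ring"].astype(str) + "/"
                   + df["plant"].astype(str) + "/" + df["shoot"].astype(str))
    max_rank = df.groupby("_unit")["r_apex"].transform("max")
    df["_size"] = pd.qcut(max_rank, 3, labels=["small", "mid", "large"],
                          duplicates="drop")
    plan = blocked_split(df, ["year", "trt", "_size"], "_unit", ratio, seed)
    mask = plan.mask(df, "_unit")
    return (df[mask].drop(columns=["_unit", "_size"]),
            df[~mask].drop(columns=["_unit", "_size"]), plan)
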