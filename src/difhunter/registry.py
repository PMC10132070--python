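"""Curated family registry and published site surveys shipped as data.

``family_registry()`` carries the curated member list of the IS1202 family
(name, host species, subgroup, element length, TIR identity label, TSD
length, transposase length). The site tables carry the published survey of
target sites: pdif sites targeted in plasmids, chromosomal dif sites
targeted, and dif-like sites associated with the non-*Acinetobacter*
members. These serve as inputs for locus reconstructions and for generator
presets.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = resources.files("difhunter") / "data"


def _load(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path, sep="\t", dtype=str)


def family_registry() -> pd.DataFrame:
    """Curated family members with per-element anatomy summary fields."""
    df = _load("family_registry.tsv")
    for col in ("length_bp", "tsd_len", "tnp_aa"):
        df[col] = df[col].astype(int)
    df[["tir_identical", "tir_len"]] = (
        df["tir"].str.split("/", expand=True).astype(int))
    return df


def registry_entry(name: str) -> pd.Series:
    df = family_registry()
    hit = df[df["name"] == name]
    if hit.empty:
        raise KeyError(f"{name!r} not in the family registry")
    return hit.iloc[0]


def pdif_site_survey() -> pd.DataFrame:
    """Published pdif sites targeted in plasmids (TSD, C, spacer, D)."""
    return _load("pdif_sites_plasmid.tsv")


def chromosomal_dif_survey() -> pd.DataFrame:
    """Published chromosomal dif sites targeted (with their 5 bp TSDs)."""
    return _load("chromosomal_dif_sites.tsv")


def diflike_site_survey() -> pd.DataFrame:
    """Published dif-like sites associated with other family members."""
    return _load("diflike_sites_other_is.tsv")


def survey_row(df: pd.DataFrame, is_name: str, accession: str) -> pd.Series:
    hit = df[(df["is_name"] == is_name) & (df["accession"] == accession)]
    if hit.empty:
        raise KeyError(f"no survey row for {is_name}/{accession}")
    return hit.iloc[0]
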