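"""File formats: FASTA/FASTQ via Biopython, TSV via pandas, JSON reports.

All emitted coordinates are 1-based inclusive; internal coordinates are
0-based half-open.  Every JSON report carries a ``schema_version`` and the
seed used, for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .design import (
    BSPQI,
    ESP3I,
    EnzymeDef,
    FragmentSpec,
    Junction,
    LibraryDesign,
    SaturationScheme,
    SaturationSite,
)

BUILTIN_ENZYMES = {e.name: e for e in (ESP3I, BSPQI)}


def read_single_fasta(path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record")
    return str(records[0].seq).upper()


def write_fasta(path, name: str, seq: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# Scheme config (YAML)
# ---------------------------------------------------------------------------

def scheme_from_config(orf: str, config: dict) -> SaturationScheme:
    """Build a scheme from an ORF string and a parsed config mapping.

    Config keys: ``sites`` (list of mappings with ``aa_position`` and
    optional ``residues`` / ``codons``), optional ``fixed_5prime``,
    ``fixed_3prime``, ``enzymes`` (names or explicit definitions).
    """
    sites = []
    for entry in config.get("sites", []):
        if isinstance(entry, int):
            entry = {"aa_position": entry}
        kwargs = {"aa_position": int(entry["aa_position"])}
        if "residues" in entry:
            kwargs["residues"] = tuple(entry["residues"])
        if "codons" in entry:
            kwargs["codon_for_residue"] = {
                str(k): str(v).upper() for k, v in entry["codons"].items()
            }
        sites.append(SaturationSite(**kwargs))
    enzymes = []
    for entry in config.get("enzymes", []):
        if isinstance(entry, str):
            enzymes.append(BUILTIN_ENZYMES[entry])
        else:
            enzymes.append(EnzymeDef(
                entry["name"], entry["recognition"].upper(),
                int(entry["spacer"]), int(entry["overhang_length"]),
            ))
    kwargs = {}
    if enzymes:
        kwargs["enzymes"] = tuple(enzymes)
    return SaturationScheme(
        orf_sequence=orf,
        sites=tuple(sites),
        fixed_5prime=str(config.get("fixed_5prime", "")).upper(),
        fixed_3prime=str(config.get("fixed_3prime", "")).upper(),
        **kwargs,
    )


def load_scheme(orf_fasta, config_path) -> tuple[SaturationScheme, dict]:
    orf = read_single_fasta(orf_fasta)
    with open(config_path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError(f"{config_path}: config must be a mapping")
    return scheme_from_config(orf, config), config


# ---------------------------------------------------------------------------
# Design JSON round trip
# ---------------------------------------------------------------------------

def _enzyme_to_dict(e: EnzymeDef) -> dict:
    return {"name": e.name, "recognition": e.recognition,
            "spacer": e.spacer, "overhang_length": e.overhang_length}


def design_to_dict(design: LibraryDesign) -> dict:
    scheme = design.scheme
    return {
        "schema_version": 1,
        "version": __version__,
        "scheme": {
            "orf_sequence": scheme.orf_sequence,
            "fixed_5prime": scheme.fixed_5prime,
            "fixed_3prime": scheme.fixed_3prime,
            "enzymes": [_enzyme_to_dict(e) for e in scheme.enzymes],
            "sites": [
                {
                    "aa_position": s.aa_position,
                    "residues": list(s.residues),
                    "codons": dict(s.codon_for_residue),
                }
                for s in scheme.sites
            ],
        },
        "junctions": [
            {
                "round_pair": list(j.round_pair),
                "position_1based": j.position + 1,
                "overhang": j.overhang,
                "enzyme": j.enzyme.name,
            }
            for j in design.junctions
        ],
        "fragment_sets": [
            [
                {
                    "role": f.role,
                    "round_index": f.round_index,
                    "site_position": f.site_position,
                    "variant_residue": f.variant_residue,
                    "top_strand": f.top_strand,
                    "bottom_strand": f.bottom_strand,
                    "upstream_overhang": f.upstream_overhang,
                    "downstream_overhang": f.downstream_overhang,
                    "stuffer": f.stuffer,
                    "modifications": sorted(f.modifications),
                }
                for f in frag_set
            ]
            for frag_set in design.fragment_sets
        ],
        "reference_construct": design.reference_construct,
    }


def design_from_dict(data: dict) -> LibraryDesign:
    s = data["scheme"]
    enzymes = tuple(
        EnzymeDef(e["name"], e["recognition"], e["spacer"], e["overhang_length"])
        for e in s["enzymes"]
    )
    scheme = SaturationScheme(
        orf_sequence=s["orf_sequence"],
        sites=tuple(
            SaturationSite(
                site["aa_position"],
                residues=tuple(site["residues"]),
                codon_for_residue=dict(site["codons"]),
            )
            for site in s["sites"]
        ),
        fixed_5prime=s["fixed_5prime"],
        fixed_3prime=s["fixed_3prime"],
        enzymes=enzymes,
    )
    by_name = {e.name: e for e in enzymes}
    junctions = tuple(
        Junction(tuple(j["round_pair"]), j["position_1based"] - 1,
                 j["overhang"], by_name[j["enzyme"]])
        for j in data["junctions"]
    )
    fragment_sets = tuple(
        tuple(
            FragmentSpec(
                role=f["role"], round_index=f["round_index"],
                site_position=f["site_position"],
                variant_residue=f["variant_residue"],
                top_strand=f["top_strand"], bottom_strand=f["bottom_strand"],
                upstream_overhang=f["upstream_overhang"],
                downstream_overhang=f["downstream_overhang"],
                stuffer=f["stuffer"],
                modifications=frozenset(f["modifications"]),
            )
            for f in frag_set
        )
        for frag_set in data["fragment_sets"]
    )
    return LibraryDesign(scheme, fragment_sets, junctions,
                         data["reference_construct"])


def save_design(design: LibraryDesign, path) -> None:
    with open(path, "w") as fh:
        json.dump(design_to_dict(design), fh, indent=1)


def load_design(path) -> LibraryDesign:
    with open(path) as fh:
        return design_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Sites / composition tables
# ---------------------------------------------------------------------------

def sites_table(scheme: SaturationScheme, offset: int = 0) -> pd.DataFrame:
    """Per-site table with 1-based nucleotide starts relative to a region
    beginning at construct coordinate ``offset`` (e.g. an amplicon)."""
    rows = []
    for i, site in enumerate(scheme.sites):
        start, _ = scheme.codon_span(site)
        wt = scheme.wild_type_residue(site)
        rows.append({
            "site": f"site_{i + 1}",
            "aa_position": site.aa_position,
            "nt_start_1based": start - offset + 1,
            "wild_type_codon": site.codon_for_residue.get(
                wt, scheme.orf_sequence[(site.aa_position - 1) * 3:
                                        (site.aa_position - 1) * 3 + 3]),
            "residues": "".join(site.residues),
        })
    return pd.DataFrame(rows)


def write_manifest(out_dir, subcommand: str, inputs: dict, params: dict,
                   seed: int | None) -> None:
    manifest = {
        "schema_version": 1,
        "tool": "splimlib",
        "version": __version__,
        "subcommand": subcommand,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": params,
        "seed": seed,
    }
    with open(Path(out_dir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
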