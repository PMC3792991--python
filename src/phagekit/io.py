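"""File-format adapters.

FASTA/GenBank via Bio.SeqIO; frequency tables as CSV (rows = amino
acids, columns = positions) or JSON; codon-usage and enzyme tables as
TSV; melt curves and ITC series as headed CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .biophys import ItcSeries, MeltingCurve
from .codontab import CodonTable
from .diversity import CdrDesign, PositionFrequency
from .seqdesign import RestrictionSite


def read_first_sequence(path: str | Path, fmt: str | None = None) -> str:
    """Read the first record of a FASTA/GenBank file as an upper-case string."""
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".genbank"} \
            else "fasta"
    record = next(SeqIO.parse(str(path), fmt))
    return str(record.seq).upper()


def load_codon_table_tsv(path: str | Path,
                         rare_threshold: float = 0.10) -> CodonTable:
    """TSV with columns: amino_acid, codon, fraction."""
    df = pd.read_csv(path, sep="\t", comment="#")
    usage: dict[str, list[tuple[str, float]]] = {}
    for _, row in df.iterrows():
        usage.setdefault(str(row["amino_acid"]).upper(), []).append(
            (str(row["codon"]).upper(), float(row["fraction"]))
        )
    return CodonTable({aa: tuple(v) for aa, v in usage.items()},
                      rare_threshold=rare_threshold)


def load_enzymes_tsv(path: str | Path) -> dict[str, RestrictionSite]:
    """TSV with columns: name, recognition."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        str(row["name"]): RestrictionSite(str(row["name"]),
                                          str(row["recognition"]))
        for _, row in df.iterrows()
    }


def load_frequency_csv(
    path: str | Path,
    name: str,
    fixed_flanks: tuple[str, str] = ("", ""),
    constraint_profile: str = "generic",
) -> CdrDesign:
    """CSV: first column amino acid one-letter codes, remaining columns
    one randomized position each (headers become position labels)."""
    df = pd.read_csv(path, index_col=0)
    positions = [
        PositionFrequency(str(col),
                          {str(aa): float(v) for aa, v in df[col].items()
                           if float(v) > 0.0})
        for col in df.columns
    ]
    return CdrDesign(name, tuple(positions), fixed_flanks, constraint_profile)


def load_frequency_json(path: str | Path) -> CdrDesign:
    """JSON with keys name, fixed_flanks, constraint_profile, positions
    (list of {label, freq})."""
    payload = json.loads(Path(path).read_text())
    positions = tuple(
        PositionFrequency(p["label"], {k: float(v) for k, v in p["freq"].items()})
        for p in payload["positions"]
    )
    flanks = tuple(payload.get("fixed_flanks", ["", ""]))
    return CdrDesign(payload["name"], positions, (flanks[0], flanks[1]),
                     payload.get("constraint_profile", "generic"))


def design_to_frame(design: CdrDesign) -> pd.DataFrame:
    """Frequency table as a DataFrame (rows = residues, cols = positions)."""
    residues = sorted({aa for pf in design.positions for aa in pf.freq})
    data = {pf.position_label: [pf.p(aa) for aa in residues]
            for pf in design.positions}
    return pd.DataFrame(data, index=residues)


def read_melting_csv(path: str | Path, ramp: str = "first") -> MeltingCurve:
    """Two-column CSV with header: temperature_C, signal."""
    df = pd.read_csv(path)
    t, s = df.iloc[:, 0], df.iloc[:, 1]
    return MeltingCurve(tuple(map(float, t)), tuple(map(float, s)), ramp=ramp)


def read_itc_csv(
    path: str | Path,
    cell_concentration: float,
    syringe_concentration: float,
    cell_volume: float,
) -> ItcSeries:
    """CSV with header: injection_volume_L, heat_J."""
    df = pd.read_csv(path)
    return ItcSeries(
        cell_concentration, syringe_concentration, cell_volume,
        tuple(map(float, df.iloc[:, 0])), tuple(map(float, df.iloc[:, 1])),
    )


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i: i + 70] + "\n")
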