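"""Plain-text readers/writers for the formats the CLI consumes."""

from __future__ import annotations

import pandas as pd

from .errors import ParseError
from .neoantigen_load import MutationRecord


def read_fasta(path: str) -> dict[str, str]:
    """Minimal FASTA reader keyed by the first token of each header."""
    seqs: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            else:
                if name is None:
                    raise ParseError(f"sequence before header in {path}")
                parts.append(line)
    if name is not None:
        seqs[name] = "".join(parts)
    return seqs


def write_fasta(seqs: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def read_mutations(path: str) -> list[MutationRecord]:
    """MAF-like TSV: sample, gene, protein_change (p.A50V), class, SIFT, PROVEAN."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        if "protein_change" in df.columns:
            change = str(row["protein_change"])
            if not change.startswith("p."):
                raise ParseError(f"bad protein change {change!r} in {path}")
            ref, pos, alt = change[2], int(change[3:-1]), change[-1]
        else:
            ref, pos, alt = row["ref"], int(row["protein_position"]), row["alt"]
        records.append(MutationRecord(
            sample=str(row["sample"]), gene=str(row["gene"]),
            protein_position=pos, ref=str(ref), alt=str(alt),
            mutation_class=str(row["class"]),
            sift_damaging=bool(row.get("sift_damaging", row.get("SIFT", False))),
            provean_deleterious=bool(
                row.get("provean_deleterious", row.get("PROVEAN", False))
            ),
        ))
    return records


def write_mutations(records, path: str) -> None:
    pd.DataFrame([{
        "sample": m.sample, "gene": m.gene,
        "protein_change": f"p.{m.ref}{m.protein_position}{m.alt}",
        "class": m.mutation_class,
        "sift_damaging": m.sift_damaging,
        "provean_deleterious": m.provean_deleterious,
    } for m in records]).to_csv(path, sep="\t", index=False)


def read_hla_table(path: str) -> dict[str, list[str]]:
    """TSV mapping sample -> comma-separated allele names."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(row["sample"]): [a.strip() for a in str(row["alleles"]).split(",") if a.strip()]
        for _, row in df.iterrows()
    }


def read_edge_list(path: str) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:2])
    return [(str(a), str(b)) for a, b in zip(df[cols[0]], df[cols[1]])]
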