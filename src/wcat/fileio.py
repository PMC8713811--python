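"""FASTA and tabular I/O helpers (thin wrappers over Biopython/pandas)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict:
    """Ordered mapping of record id to sequence string."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def calls_to_frame(calls) -> pd.DataFrame:
    """Chain calls as a tidy table (one row per chain)."""
    rows = []
    for call in calls:
        row = {
            "chain_id": call.chain_id,
            "label": call.label,
            "margin": round(call.margin, 4),
            "n_extracellular_domains": (
                call.architecture.extracellular_domain_count if call.architecture else 0
            ),
            "cptmcy_count": call.architecture.cptmcy_count if call.architecture else 0,
            "note": call.note,
        }
        for cls, score in sorted(call.scores.items()):
            row[f"score_{cls}"] = round(score, 4)
        rows.append(row)
    return pd.DataFrame(rows)


def domains_to_frame(calls) -> pd.DataFrame:
    """Per-chain domain intervals and mapping scores."""
    rows = []
    for call in calls:
        if call.architecture is None:
            continue
        for hit in call.architecture.hits:
            rows.append({
                "chain_id": call.chain_id, "frame": hit.frame,
                "start": hit.start, "end": hit.end, "score": round(hit.score, 4),
            })
        if call.architecture.tm_interval is not None:
            s, e = call.architecture.tm_interval
            rows.append({
                "chain_id": call.chain_id, "frame": "TM",
                "start": s, "end": e,
                "score": round(call.architecture.tm_hit.score, 4)
                if call.architecture.tm_hit else float("nan"),
            })
    return pd.DataFrame(rows)


def profile_to_frame(profile) -> pd.DataFrame:
    return pd.DataFrame({
        "column": range(1, profile.n_columns + 1),
        "modal_residue": [r or "-" for r in profile.modal_residue],
        "modal_fraction": [round(f, 4) for f in profile.modal_fraction],
        "entropy_bits": [round(h, 4) for h in profile.entropy_bits],
        "all_gap": profile.all_gap,
    })


def supports_to_frame(support) -> pd.DataFrame:
    rows = [
        {"clade": ",".join(sorted(split)), "support_pct": round(pct, 1)}
        for split, pct in sorted(support.supports.items(), key=lambda kv: -kv[1])
    ]
    return pd.DataFrame(rows, columns=["clade", "support_pct"])


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
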