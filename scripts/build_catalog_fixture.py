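"""Regenerate the bundled synthetic catalogue fixture.

The fixture mirrors the published 68-gene precursor table (designations,
accessions, class sections, completeness marks) but every sequence is a
synthetic stand-in built deterministically here: the deposited precursor
sequences are not redistributed. Four mature-peptide anchors whose
sequences are known from the primary literature (proctolin RYLPT, PDF
NSEIINSLLGLPKVLNDA-amide, AKH pyroGlu-VNFSPNW-amide, NVP-2 DNSQWGGFAKD)
are embedded verbatim so that their theoretical ion masses are real.

Run from the repository root:  python scripts/build_catalog_fixture.py
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parents[1] / "src" / "neuropep" / "data"

# (accession, designation, class, complete) transcribed from the published
# gene table; (+) rows are the eight incomplete precursors.
TABLE = [
    # --- neuropeptides (43) ---
    ("PQ049256", "AKH-1", "neuropeptide", True),
    ("PQ049257", "AKH-2", "neuropeptide", True),
    ("PQ049260", "ACP", "neuropeptide", True),
    ("PQ049261", "AT", "neuropeptide", True),
    ("PQ049262", "Ast-A", "neuropeptide", True),
    ("PQ049263", "MIP", "neuropeptide", True),
    ("PQ049264", "Ast-CC", "neuropeptide", True),
    ("PQ049265", "Ast-CCC", "neuropeptide", True),
    ("PQ049266", "Inotocin", "neuropeptide", True),
    ("PQ049267", "Calcitonin-B", "neuropeptide", False),
    ("PQ049268", "DH-31", "neuropeptide", True),
    ("PQ049269", "DH-46", "neuropeptide", True),
    ("PQ049270", "CAPA-PVK", "neuropeptide", True),
    ("PQ049271", "CCHa-1", "neuropeptide", True),
    ("PQ049272", "CCHa-2", "neuropeptide", True),
    ("PQ049273", "CNMa-A", "neuropeptide", False),
    ("PQ049274", "CNMa-B", "neuropeptide", True),
    ("PQ049275", "Crz", "neuropeptide", True),
    ("PQ049276", "CCAP", "neuropeptide", True),
    ("PQ049277", "CCRFa", "neuropeptide", True),
    ("PQ049278", "Elv", "neuropeptide", True),
    ("PQ049279", "FMRFa", "neuropeptide", True),
    ("PQ049282", "Hansolin", "neuropeptide", True),
    ("PQ049283", "ITG", "neuropeptide", True),
    ("PQ049286", "Kinin", "neuropeptide", True),
    ("PQ049287", "MS", "neuropeptide", True),
    ("PQ049288", "Nat", "neuropeptide", True),
    ("PQ049289", "NPF-1a", "neuropeptide", True),
    ("PQ049290", "NPF-1b", "neuropeptide", False),
    ("PQ049291", "NPF-2", "neuropeptide", True),
    ("PQ049296", "Orc-A", "neuropeptide", True),
    ("PQ049297", "Orc-B", "neuropeptide", False),
    ("PQ049298", "PDF", "neuropeptide", True),
    ("PQ049299", "PK", "neuropeptide", True),
    ("PQ049300", "Proctolin", "neuropeptide", True),
    ("PQ049301", "RFLamide", "neuropeptide", True),
    ("PQ049302", "RYamide", "neuropeptide", True),
    ("PQ049303", "sNPF", "neuropeptide", True),
    ("PQ049304", "SIFamide", "neuropeptide", True),
    ("PQ049305", "SMYamide", "neuropeptide", True),
    ("PQ049306", "SK", "neuropeptide", True),
    ("PQ049307", "TK", "neuropeptide", True),
    ("PQ049308", "Trissin", "neuropeptide", True),
    # --- neuropeptide-like (8) ---
    ("PQ049258", "ALP-1", "neuropeptide_like", True),
    ("PQ049259", "ALP-2", "neuropeptide_like", False),
    ("PQ049280", "FERLQ-like", "neuropeptide_like", True),
    ("PQ049281", "Flik", "neuropeptide_like", True),
    ("PQ049293", "NPLP-1", "neuropeptide_like", True),
    ("PQ049294", "CNPLP-1", "neuropeptide_like", True),
    ("PQ300805", "NVP-A", "neuropeptide_like", True),
    ("PQ300806", "NVP-B", "neuropeptide_like", True),
    # --- protein hormones (17) ---
    ("PQ049309", "Bursicon-alpha", "protein_hormone", False),
    ("PQ049310", "EH-1", "protein_hormone", True),
    ("PQ049311", "EH-2", "protein_hormone", True),
    ("PQ049312", "GPA", "protein_hormone", True),
    ("PQ049313", "GPB", "protein_hormone", True),
    ("PQ300807", "IDLP-A", "protein_hormone", True),
    ("PQ300808", "IDLP-B", "protein_hormone", True),
    ("PQ049316", "ILP-1", "protein_hormone", True),
    ("PQ049317", "ILP-2", "protein_hormone", True),
    ("PQ049318", "ILP-3", "protein_hormone", False),
    ("PQ049319", "ILP-4", "protein_hormone", True),
    ("PQ049320", "ILP-5", "protein_hormone", True),
    ("PQ049321", "ILP-6", "protein_hormone", True),
    ("PQ049284", "ITP", "protein_hormone", True),
    ("PQ049322", "Neuroparsin", "protein_hormone", False),
    ("PQ049323", "PTTH", "protein_hormone", True),
    ("PQ049324", "iPTH", "protein_hormone", True),
]

# literature-reconstructed mature peptides: name -> (core, amidation donor G)
ANCHORS = {
    "Proctolin": ("RYLPT", False),
    "PDF": ("NSEIINSLLGLPKVLNDA", True),
    "AKH-1": ("QVNFSPNW", True),
    "AKH-2": ("QVNFSPNW", True),
    "NVP-A": ("DNSQWGGFAKD", False),
}

INTERIOR = np.array(list("ADEFGHILMNPQSTVWY"))
FIRST = np.array(list("ADFGHILMNSTVWY"))
LAST = np.array(list("ADEFHILMNPQSTVWY"))
SIGNAL = np.array(list("AVLIMFWPGST"))


def word(rng, n):
    if n == 1:
        return str(rng.choice(FIRST))
    return (str(rng.choice(FIRST))
            + "".join(rng.choice(INTERIOR, size=max(0, n - 2)))
            + str(rng.choice(LAST)))


def build():
    rng = np.random.default_rng(68)
    fasta_lines = []
    ann_lines = ["id\tname\tsignal_end\tclass\tcomplete"]
    ov_lines = ["precursor_id\taction\tposition\tpayload"]

    for acc, name, cls, complete in TABLE:
        signal = ("".join(rng.choice(SIGNAL, size=int(rng.integers(18, 26))))
                  if complete else "")
        parts = [signal]
        pos = len(signal)

        anchor = ANCHORS.get(name)
        if cls == "protein_hormone":
            n_pep, lengths = 1, [int(rng.integers(50, 120))]
        else:
            n_pep = int(rng.integers(1, 4))
            lengths = [int(rng.integers(5, 31)) for _ in range(n_pep)]

        for j in range(n_pep):
            if anchor is not None and j == 0:
                pep, amid = anchor
            else:
                pep = word(rng, lengths[j])
                amid = cls != "protein_hormone" and rng.random() < 0.5
            start = pos + 1
            parts.append(pep)
            pos += len(pep)
            if amid:
                parts.append("G")
                pos += 1
            parts.append("KR")
            pos += 2
            if name == "Proctolin" and j == 0:
                # proctolin carries no amidation/pyroGlu signal; curated
                ov_lines.append(
                    f"{acc}\tset_role\t{start}\tbioactive_candidate")
            if j < n_pep - 1:
                spacer = word(rng, int(rng.integers(6, 18)))
                parts.append(spacer)
                pos += len(spacer)
                parts.append("KR")
                pos += 2
        seq = "".join(parts)
        fasta_lines.append(f">{acc} {name}")
        for i in range(0, len(seq), 60):
            fasta_lines.append(seq[i:i + 60])
        ann_lines.append("\t".join([
            acc, name, str(len(signal)) if complete else "", cls,
            "true" if complete else "false"]))

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "synthetic_catalog.fasta").write_text("\n".join(fasta_lines) + "\n")
    (OUT / "synthetic_catalog_annotations.tsv").write_text(
        "\n".join(ann_lines) + "\n")
    (OUT / "synthetic_catalog_overrides.tsv").write_text(
        "\n".join(ov_lines) + "\n")
    print(f"wrote {len(TABLE)} records to {OUT}")


if __name__ == "__main__":
    build()
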