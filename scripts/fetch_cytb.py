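#!/usr/bin/env python
"""Fetch the archived cytochrome-b sequences (network required).

Downloads GenBank accessions OP524750-OP525226 (402-bp cyt b fragments of
white-bellied pangolins from Cameroon, Equatorial Guinea and Gabon) via
NCBI E-utilities and writes ``data/cytb_genbank.fasta``.

Lineage partitioning (the WCA / Gab split behind
``tests/test_acceptance.py::test_cytb_reference_dataset_reproduces_reported_diversity``)
additionally needs published reference sequences for the six described
mitochondrial lineages; once a labelled reference FASTA is available, run
``pangotrace.assign_lineage`` on the downloaded alignment and write the
two groups to ``data/cytb_wca.fasta`` and ``data/cytb_gab.fasta``.
"""

import sys
import time
import urllib.request
from pathlib import Path

BASE = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
        "?db=nucleotide&rettype=fasta&retmode=text&id={ids}")
FIRST, LAST = 524750, 525226
PREFIX = "OP"
CHUNK = 100


def main():
    out = Path(__file__).resolve().parent.parent / "data"
    out.mkdir(exist_ok=True)
    target = out / "cytb_genbank.fasta"
    accs = [f"{PREFIX}{i}" for i in range(FIRST, LAST + 1)]
    with open(target, "w") as fh:
        for start in range(0, len(accs), CHUNK):
            ids = ",".join(accs[start:start + CHUNK])
            with urllib.request.urlopen(BASE.format(ids=ids),
                                        timeout=60) as resp:
                text = resp.read().decode()
            if not text.startswith(">"):
                sys.exit(f"unexpected response for batch at {start}")
            fh.write(text)
            time.sleep(0.4)          # NCBI rate limit
    print(f"wrote {target}")


if __name__ == "__main__":
    main()
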