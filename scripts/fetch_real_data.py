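#!/usr/bin/env python
"""Download the twelve ciliate mitochondrial GenBank records.

Requires network access to NCBI E-utilities; the library itself never
performs network access, and no test depends on these files.

Usage:
    python scripts/fetch_real_data.py --out data/real
"""

import argparse
import sys
import time
import urllib.request
from pathlib import Path

ACCESSIONS = [
    # complete mitochondrial genomes
    "NC_015981",  # Ichthyophthirius multifiliis
    "NC_001324",  # Paramecium aurelia
    "NC_014262",  # Paramecium caudatum
    "NC_008337",  # Tetrahymena malaccensis
    "NC_008338",  # Tetrahymena paravorax
    "NC_008339",  # Tetrahymena pigmentosa
    "NC_000862",  # Tetrahymena pyriformis
    "NC_003029",  # Tetrahymena thermophila
    # incomplete genomes
    "GQ903130",   # Moneuplotes minuta
    "GQ903131",   # Moneuplotes crassus
    "GU057832",   # Nyctotherus ovalis
    "JN383843",   # Oxytricha trifallax
]

EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&id={acc}&rettype=gbwithparts&retmode=text")


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("data/real"))
    args = ap.parse_args(argv)
    args.out.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = args.out / f"{acc}.gb"
        if dest.exists():
            print(f"{acc}: already present")
            continue
        url = EFETCH.format(acc=acc)
        print(f"{acc}: fetching ...")
        with urllib.request.urlopen(url, timeout=60) as resp:
            text = resp.read().decode()
        if not text.startswith("LOCUS"):
            raise RuntimeError(f"{acc}: unexpected response (no LOCUS line)")
        dest.write_text(text)
        time.sleep(0.5)  # NCBI rate limit courtesy
    print(f"done -> {args.out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
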