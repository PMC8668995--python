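#!/usr/bin/env python
"""Fetch protein FASTA records from NCBI by accession (network required).

The wee1kit library itself never performs network I/O; this standalone helper
retrieves real sequences for users who want to run the analysis on published
accessions instead of the bundled synthetic surrogates, e.g.::

    python scripts/fetch_ncbi.py NP_003381.1 NP_171796.1 XP_003625897.1 \
        XP_027932705.1 > wee1_inputs.fasta

Uses NCBI E-utilities; please set a contact email via --email per NCBI policy.
"""

from __future__ import annotations

import argparse
import sys
import time
import urllib.parse
import urllib.request

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch(accession: str, email: str) -> str:
    params = urllib.parse.urlencode({
        "db": "protein", "id": accession, "rettype": "fasta",
        "retmode": "text", "email": email, "tool": "wee1kit",
    })
    with urllib.request.urlopen(f"{EFETCH}?{params}", timeout=30) as resp:
        return resp.read().decode()


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("accessions", nargs="+")
    ap.add_argument("--email", default="", help="contact email for NCBI")
    args = ap.parse_args(argv)
    for i, acc in enumerate(args.accessions):
        if i:
            time.sleep(0.4)  # NCBI rate limit
        sys.stdout.write(fetch(acc, args.email))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
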