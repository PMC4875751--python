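"""Optional, network-gated retrieval of protein sequences by accession.

Never used by the test suite or the analysis drivers; it exists so a user
with network access can populate ``data/fetched/`` once and then run the
real-sequence worked example offline.
"""

from __future__ import annotations

import time
import urllib.parse
import urllib.request
from pathlib import Path

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch_protein_fasta(accessions: list[str], out_path: str | Path,
                        pause_s: float = 0.4) -> Path:
    """Download protein FASTA records from NCBI efetch into one file."""
    chunks = []
    for acc in accessions:
        query = urllib.parse.urlencode({"db": "protein", "id": acc,
                                        "rettype": "fasta", "retmode": "text"})
        with urllib.request.urlopen(f"{EFETCH}?{query}", timeout=30) as resp:
            chunks.append(resp.read().decode())
        time.sleep(pause_s)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text("".join(chunks))
    return out_path
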