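"""Ingest an archive into the searchable tag store and query it.

The store keeps the *identifiable* full tag set, one document per image,
keyed by SOPInstanceUID — this is the working surface for de-identification
analysts, never for researchers.
"""

import tempfile
from pathlib import Path

from dicomsieve import CorpusSpec, TagStore, generate_corpus, tag_equals

work = Path(tempfile.mkdtemp(prefix="store-example-"))
generate_corpus(CorpusSpec(n_patients=4, seed=1), work / "archive")

store = TagStore(work / "tags.sqlite")
report = store.load_directory(work / "archive")
print(f"load batch {report.batch}: seen={report.files_seen} "
      f"loaded={report.loaded} rejected={report.rejected}")

again = store.load_directory(work / "archive")
print(f"re-load is an upsert: loaded={again.loaded} updated={again.updated} "
      f"(store still holds {len(store)} documents)")

ct = store.query_documents(tag_equals("Modality", "CT"))
print(f"\n{len(ct)} CT documents; first study description: "
      f"{ct[0].tag('StudyDescription')!r}")
print("store stats:", store.store_stats()["by_modality"])
store.close()
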