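"""Generate a small planted-motif proteome and inspect its ground truth.

Each class carries one 4-8 residue motif; a protein annotated with a class
contains that motif verbatim somewhere in an otherwise i.i.d. sequence, so
class membership is decodable from sequence content.
"""

from gocapgan import SyntheticDesign, generate_corpus

design = SyntheticDesign(n_classes=5, n_proteins=60, min_len=60, max_len=100,
                         seed=42)
records, table, manifest = generate_corpus(design, out_dir="example_corpus")

print(f"proteins: {len(records)}   annotation pairs: {len(table.pairs)}")
print("class -> motif -> proteins annotated:")
for go, motif in manifest.motifs.items():
    print(f"  {go}  {motif:<8}  {manifest.class_counts.get(go, 0)}")
first = manifest.proteins[0]
print(f"\nexample: {first['accession']} classes={first['classes']} "
      f"motif positions={first['motif_positions']}")
# the counts above are the oracle that the annotation table must reproduce;
# files corpus.fasta / annotations.tsv / manifest.json are in example_corpus/
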