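# Toy two-unit gene cluster: a 4-region gene (TOYA) and one homologous
# pseudogene (TOYB).  Entirely synthetic; bundled for tests and examples.
schema: 1
gene: TOYA
pseudogenes: [TOYB]
regions:
  TOYA:
    - {kind: intron, ordinal: 1, span: [0, 150]}
    - {kind: exon, ordinal: 1, span: [150, 300]}
    - {kind: intron, ordinal: 2, span: [300, 450]}
    - {kind: exon, ordinal: 2, span: [450, 600]}
  TOYB:
    - {kind: intron, ordinal: 1, span: [600, 750]}
    - {kind: exon, ordinal: 1, span: [750, 900]}
    - {kind: intron, ordinal: 2, span: [900, 1050]}
    - {kind: exon, ordinal: 2, span: [1050, 1200]}
cn_neutral_region: [1250, 1550]
read_model: {read_length: 100, insert_size: 300}
identity_segments: []
mutations:
  - {pos: 200, op: "C>T", class: gene_disrupting}
  - {pos: 500, op: "G>A", class: gene_disrupting}
  - {pos: 180, op: "A>G", class: neutral}
  - {pos: 520, op: "T>C", class: neutral}
  - {pos: 350, op: "ins:AT", class: neutral}
configs:
  gene: {vector: [1, 1, 1, 1, 0, 0, 0, 0]}
  pseudo: {vector: [0, 0, 0, 0, 1, 1, 1, 1]}
  fusion51: {vector: [1, 1, 0, 0, 0, 0, 1, 1]}
  partial_del: {vector: [1, 0, 1, 1, 0, 0, 0, 0]}
  partial_dup: {vector: [1, 1, 1, 2, 0, 0, 0, 0]}
  deletion: {deletion: true}
majors:
  "*1": {config: gene, gdm: []}
  "*2": {config: gene, gdm: ["200:C>T"]}
  "*4": {config: gene, gdm: ["500:G>A"]}
minors:
  "*1A": {major: "*1", neutral: []}
  "*2A": {major: "*2", neutral: ["180:A>G"]}
  "*2B": {major: "*2", neutral: ["520:T>C"]}
  "*4A": {major: "*4", neutral: []}
  "*4C": {major: "*4", neutral: ["350:ins:AT"]}
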