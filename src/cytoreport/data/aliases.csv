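surface,canonical
CD3+ T cells,CD3
T cells,CD3
total T cells,CD3
T lymphocytes,CD3
CD4+ T cells,CD4
T-helper cells,CD4
helper T cells,CD4
CD4,CD4
CD8+ T cells,CD8
cytotoxic T cells,CD8
CD8,CD8
CD19+ B cells,CD19
B cells,CD19
B lymphocytes,CD19
CD20+ B cells,CD20
CD20+ cells,CD20
NK cells,NK
natural killer cells,NK
CD16+/CD56+ NK cells,NK
PBMC CD19+ B cells,CD19_PBMC
CD19+ PBMC B cells,CD19_PBMC
naive B cells,NAIVE
naïve B cells,NAIVE
transitional B cells,TRANSITIONAL
total memory B cells,TOTAL_MEMORY
memory B cells,TOTAL_MEMORY
non-switched memory B cells,NONSWITCHED_MEMORY
nonswitched memory B cells,NONSWITCHED_MEMORY
marginal-zone-like B cells,NONSWITCHED_MEMORY
switched-memory B cells,SWITCHED_MEMORY
switched memory B cells,SWITCHED_MEMORY
class-switched memory B cells,SWITCHED_MEMORY
IgM-only memory B cells,IGM_ONLY_MEMORY
IgM only memory B cells,IGM_ONLY_MEMORY
CD21+ B cells,CD21POS
CD21-positive B cells,CD21POS
CD21low B cells,CD21LOW
CD21-low B cells,CD21LOW
plasmablasts,PLASMABLASTS
circulating plasmablasts,PLASMABLASTS
total IgM+ B cells,TOTAL_IGM
IgM+ B cells,TOTAL_IGM
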