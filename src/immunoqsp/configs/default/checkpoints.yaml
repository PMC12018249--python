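# Default checkpoint expression profiles: which surface species sits on
# which cell type and the registry entry holding its copies/cell.
# Only CTLA4 is activation-induced; every other checkpoint is constant.
schema_version: 1
profiles:
  T:
    TCR:    {parameter: TCR_per_cell}
    PD-1:   {parameter: PD-1_per_cell}
    TIGIT:  {parameter: TIGIT_per_cell}
    LAG3:   {parameter: LAG3_per_cell}
    CTLA4:  {parameter: CTLA4_per_cell, induced: true}
    CD28:   {parameter: CD28_per_cell}
    OX40:   {parameter: OX40_per_cell}
    4-1BB:  {parameter: 4-1BB_per_cell}
  tumor:
    MHC:    {parameter: MHC_per_cell}
    MHCII:  {parameter: MHCII_per_cell}
    PD-L1:  {parameter: PD-L1_per_cell}
    CD155:  {parameter: CD155_per_cell}
  APC:
    MHC:    {parameter: MHC_per_cell_APC}
    MHCII:  {parameter: MHCII_per_cell_APC}
    PD-L1:  {parameter: PD-L1_per_cell_APC}
    CD155:  {parameter: CD155_per_cell_APC}
    CD8086: {parameter: CD8086_per_cell}
    OX40L:  {parameter: OX40L_per_cell}
    4-1BBL: {parameter: 4-1BBL_per_cell}
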