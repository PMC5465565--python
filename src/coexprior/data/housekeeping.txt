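# Default negative-control genes: widely used human housekeeping genes
# (stable expression across tissues). One symbol per line; replace with
# --controls to supply your own list.
ACTB
GAPDH
B2M
HPRT1
RPL13A
RPLP0
RPL19
RPL27
RPL30
RPL37A
RPS18
RPS13
RPS20
RPS29
TBP
TUBB
UBC
UBB
YWHAZ
PGK1
PPIA
PPIB
GUSB
TFRC
SDHA
HMBS
POLR2A
EEF1A1
EIF4A2
ATP5F1B
LDHA
NONO
PUM1
RPL4
RPL6
RPL9
RPL11
RPL32
RPS3
RPS5
RPS9
RPS11
RPS24
RPS27A
ALDOA
ENO1
GPI
TPI1
PGAM1
VIM
HSP90AB1
HSPA8
NACA
BTF3
SRP14
CANX
CALR
PSMB2
PSMB4
PSMA1
VCP
CCT3
CCT7
EIF3A
EIF3F
EIF4G2
PABPC1
SF3B1
SNRPD2
HNRNPA1
HNRNPC
PTBP1
RAN
RANBP1
ARF1
RAB7A
YWHAB
YWHAE
PFN1
CFL1
MYL6
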