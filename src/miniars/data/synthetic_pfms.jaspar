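>SYN001 RAP1_like
A [ 14 2 14 2 2 2 14 2 14 2 14 2 2 ]
C [ 2 14 2 14 14 14 2 2 2 14 2 2 2 ]
G [ 2 2 2 2 2 2 2 2 2 2 2 2 2 ]
T [ 2 2 2 2 2 2 2 14 2 2 2 14 14 ]
>SYN002 FKH_like
A [ 2 2 14 14 14 2 14 14 ]
C [ 2 2 2 2 2 14 2 2 ]
G [ 14 2 2 2 2 2 2 2 ]
T [ 2 14 2 2 2 2 2 2 ]
>SYN003 ABF1_like
A [ 2 2 14 2 2 14 2 14 2 2 ]
C [ 2 14 2 14 2 2 2 2 14 2 ]
G [ 2 2 2 2 2 2 2 2 2 14 ]
T [ 14 2 2 2 14 2 14 2 2 2 ]
>SYN004 YHP1_like
A [ 2 14 14 2 2 2 14 14 2 2 2 14 ]
C [ 2 2 2 2 2 2 2 2 2 2 2 2 ]
G [ 2 2 2 2 2 14 2 2 2 2 14 2 ]
T [ 14 2 2 14 14 2 2 2 14 14 2 2 ]
>SYN005 B2_like
A [ 14 2 2 2 2 2 14 2 2 14 14 2 ]
C [ 2 14 2 2 2 2 2 2 14 2 2 2 ]
G [ 2 2 2 2 2 2 2 14 2 2 2 2 ]
T [ 2 2 14 14 14 14 2 2 2 2 2 14 ]
>SYN006 TATA_indicator
A [ 0 1 0 1 ]
C [ 0 0 0 0 ]
G [ 0 0 0 0 ]
T [ 1 0 1 0 ]
>SYN007 dinuc_test
A [ 17 5 ]
C [ 5 9 ]
G [ 17 2 ]
T [ 4 10 ]
>SYN008 hexamer_test
A [ 4 8 6 1 0 1 ]
C [ 13 19 18 13 18 8 ]
G [ 11 12 8 5 14 6 ]
T [ 11 1 4 1 12 16 ]
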