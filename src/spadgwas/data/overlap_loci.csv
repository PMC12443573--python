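source,marker,chrom,pos,p,marker_r2_pct
measured,AX-94849392,1A,6155249,4.78E-04,10.91
predicted,AX-94492529,1A,3118443,7.13E-04,9.65
measured,AX-94620350,1B,50183860,8.79E-04,10.13
predicted,AX-95175396,1B,48568925,6.77E-04,9.88
measured,AX-179557826,2B,765138788,5.79E-04,11.01
predicted,AX-179557826,2B,765138788,8.28E-04,10.03
measured,AX-89366787,3B,8859867,8.02E-04,9.72
predicted,AX-111019347,3B,11947067,7.69E-04,10.20
measured,AX-95661558,3B,737861984,8.02E-04,9.72
predicted,AX-94494956,3B,730345453,5.02E-04,8.52
measured,AX-179560086,3B,759703505,5.18E-04,10.46
predicted,AX-112287513,3B,757299512,1.08E-04,12.68
measured,AX-111595357,4B,665552447,6.34E-04,10.26
predicted,AX-94552601,4B,666571859,1.29E-04,12.61
measured,AX-95659156,5A,422741070,3.55E-04,11.41
predicted,AX-95659156,5A,422741070,1.73E-04,11.81
measured,AX-110598576,5A,576774974,3.52E-04,11.97
predicted,AX-110618351,5A,577711097,3.00E-04,12.09
measured,AX-109475699,5B,644853755,9.45E-04,11.24
predicted,AX-111522577,5B,643465238,2.77E-04,10.95
measured,AX-110916065,5D,560023418,7.72E-04,9.48
predicted,AX-89322127,5D,560460920,4.18E-04,10.92
measured,AX-110126169,6B,121717558,8.55E-04,10.48
predicted,AX-109815710,6B,122944348,7.63E-06,18.98
measured,AX-109866357,6D,467023050,9.90E-04,9.83
predicted,AX-110434749,6D,470942157,4.16E-05,14.94
measured,AX-111530810,7A,198197404,9.79E-04,9.70
predicted,AX-109283182,7A,198787726,7.20E-04,8.16
measured,AX-95630787,7A,669185532,8.49E-04,10.48
predicted,AX-94567102,7A,666606185,9.67E-04,9.68
measured,AX-111627821,7B,333420288,6.49E-04,12.33
predicted,AX-111569286,7B,331619956,6.65E-05,15.21
measured,AX-111472616,7B,337472880,4.92E-04,10.70
predicted,AX-111668293,7B,337173355,4.61E-04,9.35
measured,AX-111629552,7B,601004348,1.51E-04,14.96
predicted,AX-110928740,7B,600838345,5.00E-04,11.35
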