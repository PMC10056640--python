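Sample	Clean Reads	Average Coverage of MNP Markers	Number of MNP Marker Detected	Cap Color	Source
XF91	8217560	20,235	145	yellow	wild
BJ92	7584880	18,428	132	yellow	wild
HB171	7272776	17,543	144	yellow	wild
YAAS6018	12684464	31,165	133	yellow	wild
BJ954	7633094	19,057	150	yellow	wild
BJ4	8252300	17,824	134	yellow	wild
WS2147	8901998	22,015	166	yellow	wild
HB54	12034098	29,346	153	yellow	wild
JL211	8716782	21,508	141	yellow	wild
HD91	11488732	28,263	153	yellow	wild
CD911G	10396374	25,940	153	yellow	wild
HB1911	7681900	19,159	122	yellow	wild
SX816	6655314	16,590	138	white	factory cultivar Zhongxing
6B25	9585640	23,870	143	white	factory cultivar Zhongxing
CHQ19	7473658	18,585	137	white	factory cultivar Zhongxing
TS816	8376310	20,840	141	white	factory cultivar Zhongxing
HX218	6678532	16,748	120	white	factory cultivar Zhongxing
CHQ2	7716738	19,252	138	white	factory cultivar Zhongxing
CH213	9069074	22,606	141	white	factory cultivar Zhongxing
CH0708	10101620	25,129	131	white	factory cultivar Zhongxing
YH217	9477522	23,555	151	white	factory cultivar Youhong
NK1301	8298778	20,665	138	white	factory cultivar Xuerong
DJ1401	8074850	20,094	135	white	factory cultivar Xuerong
XR201	8891596	22,120	132	white	factory cultivar Xuerong
RYY2112	8744304	21,595	143	yellow	factory cultivar Ruyi
YP215	7452770	18,548	128	white	factory cultivar Ruyi
T8-4	11198626	27,941	134	white	factory cultivar Kangrui
HC211	7525108	18,780	131	white	factory cultivar Hualv
JDG221	7407104	18,453	139	white	factory cultivar Guangming
E3209	7651640	19,053	132	white	factory cultivar Gangrongtai
LMPQ6	8723392	21,702	137	white	factory cultivar Gangrongtai
G1A	7270186	18,124	132	white	factory cultivar Gangrongtai
E3202	8027632	20,002	137	white	factory cultivar Gangrongtai
E3818	8273004	20,610	134	white	factory cultivar Gangrongtai
E87	9291466	23,082	136	white	factory cultivar Gangrongtai
XGF216	8798058	21,892	135	white	factory cultivar
MY1201	8029920	19,940	141	white	cultivar (Taiwan)
HG91	9004562	21,389	141	yellow	cultivar (Korea)
T011	8770926	21,975	134	white	cultivar (Japan)
XQY2117	8060156	20,159	154	yellow	cultivar (Guangdong)
HR9820	8631350	20,746	143	white	cultivar
RY833	9599096	23,888	145	white	cultivar
5Y16	7134102	17,761	134	white	cultivar
YG99	9588270	23,787	150	yellow	cultivar
CJ10	9040974	22,227	156	yellow	cultivar
BCT1	7396960	18,446	139	white	cultivar
PY7812	8825106	22,022	147	white	cultivar
F103	7472462	18,523	163	white	cultivar
FV093	8856082	22,150	122	white	cultivar
3W4	9080266	22,622	147	white	cultivar
S7	8393386	20,712	153	yellow	cultivar
YG910	8663284	21,498	155	yellow	cultivar
YG95	7334222	18,219	159	yellow	cultivar
GCF36	10356488	25,876	146	white	cultivar
CJ57	8307228	20,691	125	white	cultivar
CJ58	8636466	21,516	137	white	cultivar
LPY2113	10584644	26,393	147	yellow	cultivar
W543	8411992	20,871	135	white	cultivar
YF33	8865860	21,905	145	white	cultivar
W119	7222580	16,310	122	white	cultivar
YW6518	7632486	18,976	128	white	cultivar
S6	8391306	20,817	151	yellow	cultivar
YD48	8491296	21,116	139	white	cultivar
5C27	12126742	30,149	130	white	cultivar
CJ3	7872246	19,513	148	yellow	cultivar
EG7	11316622	28,131	144	white	cultivar
S4	18481160	45,878	164	yellow	cultivar
S5	9782768	24,268	157	yellow	cultivar
S3	10382322	25,833	150	yellow	cultivar
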