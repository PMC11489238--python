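gene,role
LIV001,target
LIV002,target
LIV003,target
LIV004,target
LIV005,target
LIV006,target
LIV007,target
LIV008,target
LIV009,target
LIV010,target
LIV011,target
LIV012,target
LIV013,target
LIV014,target
LIV015,target
LIV016,target
LIV017,target
LIV018,target
LIV019,target
LIV020,target
LIV021,target
LIV022,target
LIV023,target
LIV024,target
LIV025,target
LIV026,target
LIV027,target
LIV028,target
LIV029,target
LIV030,target
LIV031,target
LIV032,target
LIV033,target
LIV034,target
LIV035,target
LIV036,target
LIV037,target
LIV038,target
LIV039,target
LIV040,target
LIV041,target
LIV042,target
LIV043,target
LIV044,target
LIV045,target
LIV046,target
LIV047,target
LIV048,target
LIV049,target
LIV050,target
LIV051,target
LIV052,target
LIV053,target
LIV054,target
LIV055,target
LIV056,target
LIV057,target
LIV058,target
LIV059,target
LIV060,target
LIV061,target
LIV062,target
LIV063,target
LIV064,target
LIV065,target
LIV066,target
LIV067,target
LIV068,target
LIV069,target
LIV070,target
LIV071,target
LIV072,target
LIV073,target
LIV074,target
LIV075,target
LIV076,target
LIV077,target
LIV078,target
LIV079,target
LIV080,target
LIV081,target
LIV082,target
LIV083,target
LIV084,target
LIV085,target
LIV086,target
LIV087,target
LIV088,target
LIV089,target
LIV090,target
LIV091,target
LIV092,target
LIV093,target
LIV094,target
LIV095,target
LIV096,target
LIV097,target
LIV098,target
LIV099,target
LIV100,target
LIV101,target
LIV102,target
LIV103,target
LIV104,target
LIV105,target
LIV106,target
LIV107,target
LIV108,target
LIV109,target
LIV110,target
LIV111,target
LIV112,target
LIV113,target
LIV114,target
LIV115,target
LIV116,target
LIV117,target
LIV118,target
LIV119,target
LIV120,target
LIV121,target
LIV122,target
LIV123,target
LIV124,target
LIV125,target
LIV126,target
LIV127,target
LIV128,target
LIV129,target
LIV130,target
LIV131,target
LIV132,target
LIV133,target
LIV134,target
LIV135,target
LIV136,target
LIV137,target
LIV138,target
LIV139,target
LIV140,target
LIV141,target
LIV142,target
LIV143,target
LIV144,target
LIV145,target
LIV146,target
LIV147,target
LIV148,target
LIV149,target
LIV150,target
LIV151,target
LIV152,target
LIV153,target
LIV154,target
LIV155,target
LIV156,target
LIV157,target
LIV158,target
LIV159,target
LIV160,target
LIV161,target
LIV162,target
LIV163,target
LIV164,target
LIV165,target
LIV166,target
LIV167,target
LIV168,target
LIV169,target
LIV170,target
LIV171,target
LIV172,target
LIV173,target
LIV174,target
LIV175,target
LIV176,target
LIV177,target
LIV178,target
LIV179,target
LIV180,target
LIV181,target
LIV182,target
LIV183,target
LIV184,target
LIV185,target
LIV186,target
LIV187,target
LIV188,target
LIV189,target
LIV190,target
LIV191,target
LIV192,target
LIV193,target
LIV194,target
LIV195,target
LIV196,target
LIV197,target
LIV198,target
LIV199,target
LIV200,target
LIV201,target
LIV202,target
LIV203,target
LIV204,target
LIV205,target
LIV206,target
LIV207,target
LIV208,target
LIV209,target
LIV210,target
LIV211,target
LIV212,target
LIV213,target
LIV214,target
LIV215,target
LIV216,target
LIV217,target
LIV218,target
LIV219,target
LIV220,target
LIV221,target
LIV222,target
LIV223,target
LIV224,target
LIV225,target
LIV226,target
LIV227,target
LIV228,target
LIV229,target
LIV230,target
LIV231,target
LIV232,target
LIV233,target
LIV234,target
LIV235,target
LIV236,target
LIV237,target
LIV238,target
LIV239,target
LIV240,target
LIV241,target
LIV242,target
LIV243,target
LIV244,target
LIV245,target
LIV246,target
LIV247,target
LIV248,target
LIV249,target
LIV250,target
LIV251,target
LIV252,target
LIV253,target
LIV254,target
LIV255,target
LIV256,target
LIV257,target
LIV258,target
LIV259,target
LIV260,target
LIV261,target
LIV262,target
LIV263,target
LIV264,target
LIV265,target
LIV266,target
LIV267,target
LIV268,target
LIV269,target
LIV270,target
LIV271,target
LIV272,target
LIV273,target
LIV274,target
LIV275,target
LIV276,target
LIV277,target
LIV278,target
LIV279,target
LIV280,target
LIV281,target
LIV282,target
LIV283,target
LIV284,target
LIV285,target
LIV286,target
LIV287,target
LIV288,target
LIV289,target
LIV290,target
LIV291,target
LIV292,target
LIV293,target
LIV294,target
LIV295,target
LIV296,target
LIV297,target
LIV298,target
LIV299,target
LIV300,target
LIV301,target
LIV302,target
LIV303,target
LIV304,target
LIV305,target
LIV306,target
LIV307,target
LIV308,target
LIV309,target
LIV310,target
LIV311,target
LIV312,target
LIV313,target
LIV314,target
LIV315,target
LIV316,target
LIV317,target
LIV318,target
LIV319,target
LIV320,target
LIV321,target
LIV322,target
LIV323,target
LIV324,target
LIV325,target
LIV326,target
LIV327,target
LIV328,target
LIV329,target
LIV330,target
LIV331,target
LIV332,target
LIV333,target
LIV334,target
LIV335,target
LIV336,target
LIV337,target
LIV338,target
LIV339,target
LIV340,target
LIV341,target
LIV342,target
LIV343,target
LIV344,target
LIV345,target
LIV346,target
LIV347,target
LIV348,target
LIV349,target
LIV350,target
LIV351,target
LIV352,target
LIV353,target
LIV354,target
LIV355,target
LIV356,target
LIV357,target
LIV358,target
LIV359,target
LIV360,target
LIV361,target
LIV362,target
LIV363,target
LIV364,target
LIV365,target
LIV366,target
LIV367,target
LIV368,target
LIV369,target
LIV370,target
ACTB,housekeeping
B2M,housekeeping
GAPDH,housekeeping
HPRT1,housekeeping
RPLP0,housekeeping
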