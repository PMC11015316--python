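"""Optional HTTP transport adapter (stdlib only; no retries here).

GET requests append the rendered payload as a query string; POST requests
send it as a JSON body. Timeouts and retry policy are adapter concerns —
this minimal adapter applies a single timeout and maps any network or
decode failure to :class:`~fedkg.errors.TransportError` so the executor's
per-operation error isolation applies unchanged.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.request

from .errors import TransportError
from .executor import Request

__all__ = ["HttpTransport"]


class HttpTransport:
    def __init__(self, timeout: float = 30.0) -> None:
        self.timeout = timeout

    def call(self, request: Request):
        url = request.server_url.rstrip("/") + request.path
        try:
            if request.method == "GET":
                req = urllib.request.Request(url + "?" + request.payload)
            else:
                req = urllib.request.Request(
                    url,
                    data=request.payload.encode("utf-8"),
                    headers={"Content-Type": "application/json"},
                    method="POST",
                )
            with urllib.request.urlopen(req, timeout=self.timeout) as response:
                return json.loads(response.read().decode("utf-8"))
        except (urllib.error.URLError, OSError, ValueError) as exc:
            raise TransportError(f"{request.op_id}: {exc}") from exc
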